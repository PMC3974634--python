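"""Retention-profile figure: frequency vs signed distance with fitted curves."""

from __future__ import annotations

import numpy as np

from .retention import RetentionProfile, fit_retention_model


def plot_retention_profile(profile: RetentionProfile, path: str) -> None:
    """Scatter of retention frequency vs signed marker distance.

    Draws both the per-arm linear fit and, where it converges, the
    exponential fit, mirroring the way retention gradients are presented
    in the gene-targeting literature (cassette at x = 0).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    d = [r.signed_distance for r in profile.rows if r.n_total > 0]
    f = [r.freq for r in profile.rows if r.n_total > 0]
    ax.scatter(d, f, color="k", zorder=3, label="markers")
    for arm, sign in (("LEFT", -1), ("RIGHT", 1)):
        du, _ = profile.arm_points(arm)
        if len(du) < 3:
            continue
        xs = np.linspace(0, du.max(), 100)
        lin = fit_retention_model(profile, arm, "LINEAR")
        ax.plot(
            sign * xs,
            lin.params["slope"] * xs + lin.params["intercept"],
            color="tab:blue",
            label="linear" if arm == "LEFT" else None,
        )
        try:
            ex = fit_retention_model(profile, arm, "EXPONENTIAL")
        except ValueError:
            continue
        ax.plot(
            sign * xs,
            ex.params["amplitude"] * np.exp(-ex.params["decay_rate"] * xs),
            color="tab:orange",
            linestyle="--",
            label="exponential" if arm == "LEFT" else None,
        )
    ax.axvline(0, color="0.6", linewidth=1)
    ax.set_xlabel("signed distance from cassette (bp)")
    ax.set_ylabel("retention frequency")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(loc="lower left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
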