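"""Synthetic study designs: fixture marker maps, mechanism mixtures, noise.

The default map reproduces the marker roster of the *HPRT* targeting
system this package models: four restriction-site SNPs and one hairpin per
homology arm, with a NEO cassette between the arms.  The literature gives
only two marker positions explicitly (NcoI at -547 bp and SacI at +261 bp)
plus the two nuclease knock-in positions (-569 and +266); the remaining
fixture positions are package choices consistent with the published
inner-to-outer marker ordering, and every position is configurable.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np

from .markers import (
    CloneRecord,
    CloneTable,
    Marker,
    MarkerMap,
    SimParams,
    validate_map,
)
from .simulate import (
    Mode,
    simulate_double_event_mixture,
    simulate_ends_in,
    simulate_ends_out,
    simulate_random_integration,
    simulate_ssa,
)

__all__ = [
    "DEFAULT_MARKERS",
    "DSB_RIGHT_POSITION",
    "DSB_LEFT_POSITION",
    "make_default_map",
    "generate_mixture",
    "add_noise",
]

#: Inner-to-outer fixture roster; only NcoI and SacI positions are published.
DEFAULT_MARKERS: tuple[tuple[str, str, int, str], ...] = (
    ("AseI", "LEFT", 300, "SNP"),
    ("NcoI", "LEFT", 547, "SNP"),
    ("LHP", "LEFT", 650, "HAIRPIN"),
    ("EcoRI", "LEFT", 800, "SNP"),
    ("NdeI", "LEFT", 950, "SNP"),
    ("SspI", "RIGHT", 130, "SNP"),
    ("SacI", "RIGHT", 261, "SNP"),
    ("RHP", "RIGHT", 400, "HAIRPIN"),
    ("XbaI", "RIGHT", 600, "SNP"),
    ("SbfI", "RIGHT", 800, "SNP"),
)

#: Nuclease (I-SceI) knock-in positions used by the ends-in experiments.
DSB_RIGHT_POSITION = 266
DSB_LEFT_POSITION = 569


def make_default_map(
    arm_length_left: int = 1000,
    arm_length_right: int = 1000,
    half_site: Optional[Literal["LEFT", "RIGHT"]] = None,
) -> MarkerMap:
    """The 10-marker fixture map (4 SNPs + 1 hairpin per arm).

    ``half_site`` optionally adds an 11th HALF_SITE marker at the nuclease
    knock-in position of that arm (+266 on the right, -569 on the left).

    Raises
    ------
    ValueError
        If an arm is shorter than its outermost fixture marker.
    """
    markers = [Marker(i, a, d, k) for i, a, d, k in DEFAULT_MARKERS]
    if half_site == "RIGHT":
        markers.append(Marker("ISceI-R", "RIGHT", DSB_RIGHT_POSITION, "HALF_SITE"))
    elif half_site == "LEFT":
        markers.append(Marker("ISceI-L", "LEFT", DSB_LEFT_POSITION, "HALF_SITE"))
    elif half_site is not None:
        raise ValueError(f"half_site must be LEFT, RIGHT or None, got {half_site!r}")
    mm = MarkerMap(
        markers=markers,
        arm_length_left=arm_length_left,
        arm_length_right=arm_length_right,
        cassette_id="NEO",
    )
    problems = validate_map(mm)
    if problems:
        raise ValueError("default map invalid for these arm lengths: " + "; ".join(problems))
    return mm


_SIMULATORS = {
    "ENDS_OUT": lambda mm, p, mode, q: simulate_ends_out(mm, p, mode=mode),
    "SSA": lambda mm, p, mode, q: simulate_ssa(mm, p, mode=mode),
    "ENDS_IN": lambda mm, p, mode, q: simulate_ends_in(mm, p),
    "RANDOM_INTEGRATION": lambda mm, p, mode, q: simulate_random_integration(mm, p),
    "DOUBLE_EVENT": lambda mm, p, mode, q: simulate_double_event_mixture(mm, p, q),
}


def generate_mixture(
    marker_map: MarkerMap,
    components: Sequence[tuple[str, Optional[SimParams], float]],
    n: int,
    seed: int = 0,
    mode: Mode = "COLONY",
    double_event_q: float = 0.0,
) -> CloneTable:
    """Draw ``n`` clones from a weighted mixture of mechanism simulators.

    ``components`` is a sequence of ``(mechanism, params, weight)``;
    mechanism is one of ENDS_OUT, SSA, ENDS_IN, RANDOM_INTEGRATION,
    DOUBLE_EVENT, params may be None to use defaults, and the weights must
    sum to 1.  Ground-truth mechanism labels are preserved on every clone
    and the emitted order is a random interleaving.
    """
    if not components:
        raise ValueError("mixture needs at least one component")
    weights = np.array([w for _, _, w in components], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"component weights must be >= 0 and sum to 1, got {weights}")
    for mech, _, _ in components:
        if mech not in _SIMULATORS:
            raise ValueError(f"unknown mechanism {mech!r}")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    clones: list[CloneRecord] = []
    for (mech, params, _), k in zip(components, counts):
        if k == 0:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p = (params or SimParams(n_clones=k)).with_(n_clones=int(k), seed=sub_seed)
        table = _SIMULATORS[mech](marker_map, p, mode, double_event_q)
        clones.extend(table.clones)
    order = rng.permutation(len(clones))
    clones = [clones[i] for i in order]
    for i, c in enumerate(clones):
        c.clone_id = f"mixt{i:05d}"
    return CloneTable(
        map=marker_map,
        clones=clones,
        provenance=f"generate_mixture n={n} seed={seed} components="
        + ",".join(f"{m}:{w}" for m, _, w in components),
        meta={"seed": seed, "counts": counts.tolist()},
    )


def add_noise(
    table: CloneTable,
    error_rate: float,
    missing_rate: float,
    seed: int = 0,
) -> CloneTable:
    """Inject genotyping noise into a clone table (a copy; truth untouched).

    Independently per call: with probability ``missing_rate`` the call
    becomes N; otherwise with probability ``error_rate`` it is replaced by
    a uniformly random *different* call from {V, C, S}.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    noisy: list[CloneRecord] = []
    for clone in table.clones:
        calls = {}
        for mid, call in clone.calls.items():
            u = rng.random()
            if u < missing_rate:
                calls[mid] = "N"
            elif u < missing_rate + (1 - missing_rate) * error_rate:
                options = [c for c in "VCS" if c != call]
                calls[mid] = options[rng.integers(0, len(options))]
            else:
                calls[mid] = call
        noisy.append(
            CloneRecord(
                clone_id=clone.clone_id,
                calls=calls,
                half_site_present=clone.half_site_present,
                selected=clone.selected,
                truth_mechanism=clone.truth_mechanism,
                parent_id=clone.parent_id,
                subclone_calls=clone.subclone_calls,
            )
        )
    return CloneTable(
        map=table.map,
        clones=noisy,
        provenance=table.provenance
        + f" + noise(error={error_rate}, missing={missing_rate}, seed={seed})",
        meta=dict(table.meta),
    )
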