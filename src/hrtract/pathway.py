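"""DSBR vs SDSA/dissolution pathway calls and MMR efficiency calibration.

For DSB-induced (ends-in) targeting, double-HJ resolution (DSBR) destroys
the nuclease recognition site entirely and can retain markers distal to
the break, whereas SDSA and HJ dissolution — which leave identical marker
signatures and are treated as one ALT pathway — retain one half of the
site and lose every distal marker.  The half-site is therefore the sole
discriminator between the pathways, and a clone carrying the half-site
together with a retained distal marker is flagged as inconsistent (a
useful genotyping-noise sentinel).

Mismatch-repair anti-recombination is an event-level veto: each mismatch
in the heteroduplex independently triggers rejection with probability
``r``, so an event with ``m`` mismatches survives with ``(1-r)**m``.  An
MMR-proficient host (MLH1+) suppresses efficiency by a further
multiplicative factor.  ``calibrate_rejection`` inverts the survival
ratio of two vectors differing only in mismatch count to recover ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .markers import CloneRecord, Dsb, MarkerMap

__all__ = [
    "PathwayCall",
    "MmrModel",
    "classify_pathway",
    "calibrate_rejection",
    "relative_efficiency",
    "monte_carlo_efficiency",
]

Host = Literal["DEFICIENT", "PROFICIENT"]


@dataclass(frozen=True)
class PathwayCall:
    clone_id: str
    call: Literal["DSBR", "ALT", "INCONSISTENT"]
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class MmrModel:
    """Calibrated mismatch-repair anti-recombination parameters.

    ``r_reject`` is the per-mismatch event-rejection probability in the
    (MMR-reduced) reference host; ``host_suppression`` the extra fold
    penalty in an MMR-proficient host, defaulting to the reported lower
    bound of 50.
    """

    r_reject: float
    host_suppression: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_reject < 1.0):
            raise ValueError(f"r_reject must be in [0, 1), got {self.r_reject}")
        if self.host_suppression < 1.0:
            raise ValueError("host_suppression must be >= 1")


def classify_pathway(
    clone: CloneRecord, marker_map: MarkerMap, dsb: Dsb
) -> PathwayCall:
    """Classify one ends-in clone as DSBR, ALT, or INCONSISTENT.

    ALT requires the retained half-site *and* loss of every SNP/hairpin
    marker distal to the DSB on the DSB arm; a clone without the half-site
    is DSBR; a half-site clone retaining a distal marker is impossible
    under either model and comes back INCONSISTENT.
    """
    half = marker_map.half_site
    if half is None:
        raise ValueError("map has no HALF_SITE marker; cannot classify pathway")
    if half.arm != dsb.arm or half.distance != dsb.position:
        raise ValueError(
            f"HALF_SITE marker at {half.arm}:{half.distance} does not match "
            f"the DSB at {dsb.arm}:{dsb.position}"
        )
    distal = [
        m
        for m in marker_map.genotyped_markers
        if m.arm == dsb.arm and m.distance > dsb.position
    ]
    retained_distal = [m.id for m in distal if clone.calls.get(m.id) in ("V", "S")]

    if not clone.half_site_present:
        return PathwayCall(clone.clone_id, "DSBR", ("half-site absent",))
    if not retained_distal:
        return PathwayCall(
            clone.clone_id,
            "ALT",
            ("half-site retained", "all markers distal to the DSB lost"),
        )
    return PathwayCall(
        clone.clone_id,
        "INCONSISTENT",
        (
            "half-site retained",
            f"distal markers retained: {', '.join(retained_distal)}",
        ),
    )


def calibrate_rejection(
    efficiency_ratio: float, m_large: int, m_small: int
) -> float:
    """Per-mismatch rejection probability from a two-vector efficiency ratio.

    Given that a vector with ``m_small`` mismatches targets
    ``efficiency_ratio``-fold more efficiently than one with ``m_large``
    mismatches in the same host, solves
    ``(1-r)**(m_small - m_large) = efficiency_ratio`` for
    ``r = 1 - efficiency_ratio**(-1/(m_large - m_small))``.

    A ratio of at most 1 is outside the rejection model; it returns 0 with
    a warning rather than raising.
    """
    if m_large <= m_small or m_small < 0:
        raise ValueError("need m_large > m_small >= 0")
    if efficiency_ratio <= 1.0:
        warnings.warn(
            f"efficiency ratio {efficiency_ratio} <= 1 implies no mismatch "
            "rejection; returning r = 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - efficiency_ratio ** (-1.0 / (m_large - m_small))


def relative_efficiency(model: MmrModel, vector_m: int, host: Host = "DEFICIENT") -> float:
    """Expected targeting efficiency relative to a mismatch-free vector.

    ``(1-r)**m``, divided by the host-suppression factor in an
    MMR-proficient host.  This closed form is what the Monte-Carlo
    acceptance rate of the simulators converges to under the same
    parameters.
    """
    if vector_m < 0:
        raise ValueError("mismatch count must be >= 0")
    if host not in ("DEFICIENT", "PROFICIENT"):
        raise ValueError(f"unknown host status {host!r}")
    eff = (1.0 - model.r_reject) ** vector_m
    if host == "PROFICIENT":
        eff /= model.host_suppression
    return eff


def monte_carlo_efficiency(
    model: MmrModel,
    vector_m: int,
    host: Host = "DEFICIENT",
    n_events: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Empirical per-event acceptance rate over ``n_events`` simulated events.

    Each event survives MMR with probability ``relative_efficiency(...)``;
    the returned rate is the fraction of survivors.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = relative_efficiency(model, vector_m, host)
    accepted = int(rng.binomial(n_events, p))
    return accepted / n_events
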