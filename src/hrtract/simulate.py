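"""Forward simulation of gene-targeting recombination mechanisms.

Each simulator emits a :class:`~hrtract.markers.CloneTable` of
selection-surviving clones.  The shared geometric assumption, supported by
the linear marker-retention gradients this package analyses, is that
strand-crossover / Holliday-junction resolution positions are uniformly
distributed over the available homology interval.

Mechanisms
----------
ends-out DSBR
    The vector's two outward-facing ends invade the intact chromosome; a
    double-HJ intermediate forms on each arm.  Two independent strand
    crossovers per arm bound the heteroduplex tract.  SEGREGANT mode
    reports the genotype of one mitotic daughter (a clone picked after
    segregation); COLONY mode reports the in-situ colony, where markers
    inside the heteroduplex appear sectored and the two daughters adopt a
    trans configuration across the arms.
single-strand assimilation
    One viral strand anneals into chromosomal heteroduplex; drug selection
    kills the non-assimilated daughter, so colonies are never sectored.
    The marginal retention law is identical to an ends-out segregant.
ends-in DSBR / ALT
    A chromosomal DSB near the locus inverts the reaction: the broken
    chromosome ends resect and invade the vector.  Double-HJ resolution
    (DSBR) places the distal crossover uniformly between the DSB and the
    arm end and the proximal crossover uniformly over the remaining
    homology; only events whose conversion tract covers the cassette
    survive selection.  The alternative pathway (SDSA or HJ dissolution —
    indistinguishable by marker pattern) retains half of the nuclease site
    and loses every marker distal to the DSB.
random integration
    The vector inserts elsewhere with both homology arms intact: every
    marker is retained.
double-event mixture
    A colony is founded either by one ends-out event (trans sectoring by
    construction) or by two independent events (trans or cis with equal
    probability); used to calibrate the trans:cis subcloning statistic.

Mismatch-repair anti-recombination is modelled as event-level rejection
with probability ``1 - (1 - r)**m`` (``m`` mismatches in the heteroduplex),
times a further ``host_suppression``-fold penalty in an MMR-proficient
host.  Rejection changes how many attempts are needed, never the tract
geometry; rejected events are redrawn until the requested number of
accepted clones exists, and the attempt count is reported in the table
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .markers import (
    Arm,
    CloneRecord,
    CloneTable,
    MarkerMap,
    Mechanism,
    SimParams,
)

__all__ = [
    "EventTrace",
    "Mode",
    "simulate_ends_out",
    "simulate_ssa",
    "simulate_ends_in",
    "simulate_random_integration",
    "simulate_double_event_mixture",
    "subclone_colony",
    "spell_check_heteroduplex",
    "mmr_acceptance_probability",
]

Mode = Literal["SEGREGANT", "COLONY"]


@dataclass(frozen=True)
class EventTrace:
    """Latent geometry of one simulated recombination event.

    ``x_top``/``x_bot`` are the per-arm strand-crossover positions (bp from
    the cassette junction) for mechanisms with a heteroduplex on both
    strands; for single-crossover mechanisms the two coincide.  Ends-in
    events instead record the proximal resolution point ``p`` (signed bp)
    and the distal resolution point ``y`` (bp on the DSB arm).
    """

    mechanism: Mechanism
    x_top_left: Optional[float] = None
    x_bot_left: Optional[float] = None
    x_top_right: Optional[float] = None
    x_bot_right: Optional[float] = None
    proximal: Optional[float] = None  # signed bp; ends-in only
    distal: Optional[float] = None  # bp on the DSB arm; ends-in only
    pathway: Optional[Literal["DSBR", "ALT"]] = None
    accepted: bool = True
    rejection_reason: Optional[Literal["selection", "mmr"]] = None


def mmr_acceptance_probability(params: SimParams) -> float:
    """Probability that one event survives mismatch-repair surveillance."""
    p = (1.0 - params.r_reject) ** params.n_mismatches
    if params.host == "PROFICIENT":
        p /= params.host_suppression
    return p


def _attempts_for(rng: np.random.Generator, n_accepted: int, p_accept: float) -> int:
    # Number of Bernoulli(p) trials needed for n successes.  Geometry is
    # independent of MMR acceptance, so rejected events need not be
    # materialised; the attempt count is sampled from the exact law.
    if p_accept >= 1.0 or n_accepted == 0:
        return n_accepted
    return n_accepted + int(rng.negative_binomial(n_accepted, p_accept))


def _marker_arrays(marker_map: MarkerMap):
    markers = marker_map.genotyped_markers
    ids = [m.id for m in markers]
    arms = np.array([m.arm == "LEFT" for m in markers])  # True = LEFT
    dist = np.array([float(m.distance) for m in markers])
    return ids, arms, dist


def _calls_from_codes(ids: list[str], codes: np.ndarray) -> dict[str, str]:
    sym = "VCSN"
    return {mid: sym[c] for mid, c in zip(ids, codes)}


def _build_table(
    marker_map: MarkerMap,
    records: list[CloneRecord],
    provenance: str,
    params: SimParams,
    attempts: int,
) -> CloneTable:
    meta = {
        "params": params,
        "attempts": attempts,
        "acceptance_rate": (len(records) / attempts) if attempts else 1.0,
    }
    return CloneTable(map=marker_map, clones=records, provenance=provenance, meta=meta)


def simulate_ends_out(
    marker_map: MarkerMap,
    params: SimParams,
    mode: Mode = "SEGREGANT",
) -> CloneTable:
    """Simulate ends-out double-HJ gene targeting.

    Per accepted event and per arm, two independent strand crossovers
    ``x_top, x_bot ~ Uniform(0, L)`` bound the heteroduplex.  In SEGREGANT
    mode one strand is chosen at random per arm and a marker at distance
    ``d`` is viral iff ``d < x``; in COLONY mode markers inside the
    heteroduplex are sectored, and the two daughter genotypes are paired in
    trans across the arms (the daughter with the longer viral tract on one
    arm carries the shorter tract on the other).
    """
    if params.dsb is not None:
        raise ValueError("ends-out simulation takes no DSB; use simulate_ends_in")
    if mode not in ("SEGREGANT", "COLONY"):
        raise ValueError(f"unknown mode {mode!r}")
    params.validate_against(marker_map)
    rng = np.random.default_rng(params.seed)
    n = params.n_clones
    attempts = _attempts_for(rng, n, mmr_acceptance_probability(params))

    ids, is_left, dist = _marker_arrays(marker_map)
    L_left = float(marker_map.arm_length_left)
    L_right = float(marker_map.arm_length_right)

    if params.crossover_law == "IID":
        x_left = rng.uniform(0.0, L_left, size=(n, 2))
        x_right = rng.uniform(0.0, L_right, size=(n, 2))
    else:  # FIXED_TRACT: second crossover a fixed span outward from the first
        t = float(params.tract_length)  # type: ignore[arg-type]
        x0l = rng.uniform(0.0, L_left, size=n)
        x0r = rng.uniform(0.0, L_right, size=n)
        x_left = np.column_stack([x0l, np.minimum(x0l + t, L_left)])
        x_right = np.column_stack([x0r, np.minimum(x0r + t, L_right)])

    records: list[CloneRecord] = []
    if mode == "SEGREGANT":
        pick_l = rng.integers(0, 2, size=n)
        pick_r = rng.integers(0, 2, size=n)
        xl = x_left[np.arange(n), pick_l]
        xr = x_right[np.arange(n), pick_r]
        chosen = np.where(is_left[None, :], xl[:, None], xr[:, None])
        codes = np.where(dist[None, :] < chosen, 0, 1)  # V else C
        for i in range(n):
            records.append(
                CloneRecord(
                    clone_id=f"eo{i:05d}",
                    calls=_calls_from_codes(ids, codes[i]),
                    truth_mechanism="ENDS_OUT_DSBR",
                    trace=EventTrace(
                        mechanism="ENDS_OUT_DSBR",
                        x_top_left=float(x_left[i, 0]),
                        x_bot_left=float(x_left[i, 1]),
                        x_top_right=float(x_right[i, 0]),
                        x_bot_right=float(x_right[i, 1]),
                    ),
                )
            )
    else:
        lo_l, hi_l = x_left.min(axis=1), x_left.max(axis=1)
        lo_r, hi_r = x_right.min(axis=1), x_right.max(axis=1)
        lo = np.where(is_left[None, :], lo_l[:, None], lo_r[:, None])
        hi = np.where(is_left[None, :], hi_l[:, None], hi_r[:, None])
        codes = np.where(dist[None, :] < lo, 0, np.where(dist[None, :] < hi, 2, 1))
        # Trans pairing: daughter A takes the long viral tract on the left
        # arm and the short one on the right; daughter B the reciprocal.
        xa = np.where(is_left[None, :], hi_l[:, None], lo_r[:, None])
        xb = np.where(is_left[None, :], lo_l[:, None], hi_r[:, None])
        codes_a = np.where(dist[None, :] < xa, 0, 1)
        codes_b = np.where(dist[None, :] < xb, 0, 1)
        for i in range(n):
            records.append(
                CloneRecord(
                    clone_id=f"eo{i:05d}",
                    calls=_calls_from_codes(ids, codes[i]),
                    truth_mechanism="ENDS_OUT_DSBR",
                    subclone_calls=(
                        _calls_from_codes(ids, codes_a[i]),
                        _calls_from_codes(ids, codes_b[i]),
                    ),
                    trace=EventTrace(
                        mechanism="ENDS_OUT_DSBR",
                        x_top_left=float(x_left[i, 0]),
                        x_bot_left=float(x_left[i, 1]),
                        x_top_right=float(x_right[i, 0]),
                        x_bot_right=float(x_right[i, 1]),
                    ),
                )
            )
    return _build_table(
        marker_map, records, f"simulate_ends_out mode={mode}", params, attempts
    )


def simulate_ssa(
    marker_map: MarkerMap,
    params: SimParams,
    mode: Mode = "COLONY",
) -> CloneTable:
    """Simulate single-strand assimilation.

    One viral strand is assimilated per arm with a single crossover
    ``~ Uniform(0, L)``; the non-assimilated daughter dies under selection,
    so colonies are unsectored and both modes yield V/C calls only.  The
    marginal retention law matches an ends-out segregant.
    """
    if params.dsb is not None:
        raise ValueError("assimilation simulation takes no DSB")
    params.validate_against(marker_map)
    rng = np.random.default_rng(params.seed)
    n = params.n_clones
    attempts = _attempts_for(rng, n, mmr_acceptance_probability(params))

    ids, is_left, dist = _marker_arrays(marker_map)
    xl = rng.uniform(0.0, float(marker_map.arm_length_left), size=n)
    xr = rng.uniform(0.0, float(marker_map.arm_length_right), size=n)
    x = np.where(is_left[None, :], xl[:, None], xr[:, None])
    codes = np.where(dist[None, :] < x, 0, 1)

    records = []
    for i in range(n):
        calls = _calls_from_codes(ids, codes[i])
        records.append(
            CloneRecord(
                clone_id=f"ssa{i:05d}",
                calls=calls,
                truth_mechanism="SSA_ASSIMILATION",
                subclone_calls=(dict(calls), dict(calls)),
            )
        )
    return _build_table(
        marker_map, records, f"simulate_ssa mode={mode}", params, attempts
    )


def simulate_ends_in(marker_map: MarkerMap, params: SimParams) -> CloneTable:
    """Simulate DSB-induced ends-in gene targeting.

    Requires ``params.dsb`` at position ``s`` strictly inside one arm.
    ``p_alt`` is the fraction of *selection-surviving* clones produced by
    the ALT pathway (SDSA/HJ dissolution), matching how a pathway fraction
    is measured in vivo; the remainder are DSBR:

    * DSBR — distal resolution ``y ~ Uniform(s, L)`` on the DSB arm;
      proximal resolution ``p`` uniform over the homology from the far arm
      end to ``s`` (signed coordinates).  The event survives selection iff
      the conversion tract covers the cassette, i.e. ``p`` lies on the far
      side of the cassette; failing events are redrawn and counted as
      attempts.  Markers between ``p`` and ``y`` are viral.  Every marker
      between the cassette and the DSB is therefore retained in 100% of
      accepted clones.
    * ALT — the chromosome copies the vector exactly up to the DSB: half
      of the nuclease site is retained (``half_site_present``), markers
      between cassette and DSB are viral, all markers distal to the DSB
      are chromosomal; the far arm follows the same proximal law
      conditioned on covering the cassette (an ALT clone only exists if it
      acquired the cassette).
    """
    if params.dsb is None:
        raise ValueError("ends-in simulation requires params.dsb")
    params.validate_against(marker_map)
    rng = np.random.default_rng(params.seed)
    n = params.n_clones

    dsb = params.dsb
    s = float(dsb.position)
    L_dsb = float(marker_map.arm_length(dsb.arm))
    other_arm: Arm = "LEFT" if dsb.arm == "RIGHT" else "RIGHT"
    L_other = float(marker_map.arm_length(other_arm))

    ids, is_left, dist = _marker_arrays(marker_map)
    on_dsb_arm = is_left if dsb.arm == "LEFT" else ~is_left

    is_alt = rng.random(n) < params.p_alt
    # Accepted-event geometry: p | (covers cassette) ~ Uniform(-L_other, 0),
    # independent of y ~ Uniform(s, L_dsb).
    p = -rng.uniform(0.0, L_other, size=n)
    y = rng.uniform(s, L_dsb, size=n)

    # Attempt bookkeeping: each DSBR clone needed Geometric redraws against
    # the selection filter P(p < 0) = L_other / (L_other + s); every
    # attempt of either pathway additionally had to survive MMR.
    p_sel = L_other / (L_other + s)
    p_mmr = mmr_acceptance_probability(params)
    n_alt = int(is_alt.sum())
    attempts = n
    attempts += _attempts_for(rng, n_alt, p_mmr) - n_alt if n_alt else 0
    n_dsbr = n - n_alt
    attempts += (
        _attempts_for(rng, n_dsbr, p_mmr * p_sel) - n_dsbr if n_dsbr else 0
    )

    upper = np.where(is_alt, s, y)  # viral tract end on the DSB arm
    viral = np.where(on_dsb_arm[None, :], dist[None, :] < upper[:, None], dist[None, :] < -p[:, None])
    codes = np.where(viral, 0, 1)

    records: list[CloneRecord] = []
    for i in range(n):
        alt = bool(is_alt[i])
        records.append(
            CloneRecord(
                clone_id=f"ei{i:05d}",
                calls=_calls_from_codes(ids, codes[i]),
                half_site_present=alt,
                truth_mechanism="ENDS_IN_ALT" if alt else "ENDS_IN_DSBR",
                trace=EventTrace(
                    mechanism="ENDS_IN_ALT" if alt else "ENDS_IN_DSBR",
                    proximal=float(p[i]) if dsb.arm == "RIGHT" else -float(p[i]),
                    distal=float(upper[i]),
                    pathway="ALT" if alt else "DSBR",
                ),
            )
        )
    return _build_table(
        marker_map,
        records,
        f"simulate_ends_in dsb={dsb.arm}:{dsb.position}",
        params,
        attempts,
    )


def simulate_random_integration(marker_map: MarkerMap, params: SimParams) -> CloneTable:
    """Simulate random integration: both homology arms insert intact."""
    ids = [m.id for m in marker_map.genotyped_markers]
    records = [
        CloneRecord(
            clone_id=f"ri{i:05d}",
            calls={mid: "V" for mid in ids},
            truth_mechanism="RANDOM_INTEGRATION",
        )
        for i in range(params.n_clones)
    ]
    return _build_table(
        marker_map, records, "simulate_random_integration", params, params.n_clones
    )


def simulate_double_event_mixture(
    marker_map: MarkerMap,
    params: SimParams,
    q: float,
) -> CloneTable:
    """Simulate colonies founded by one or two independent targeting events.

    With probability ``1 - q`` a colony arises from a single ends-out
    COLONY event (trans sectoring by construction); with probability ``q``
    it is assembled from two independent segregant genotypes, whose
    arm-sector orientation is then cis or trans with equal probability.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"double-event fraction q must be in [0, 1], got {q}")
    params.validate_against(marker_map)
    rng = np.random.default_rng(params.seed)
    n = params.n_clones

    ids, is_left, dist = _marker_arrays(marker_map)
    L_left = float(marker_map.arm_length_left)
    L_right = float(marker_map.arm_length_right)

    is_double = rng.random(n) < q
    n_single = int((~is_double).sum())
    singles = simulate_ends_out(
        marker_map,
        params.with_(n_clones=n_single, seed=int(rng.integers(0, 2**31 - 1))),
        mode="COLONY",
    ).clones

    records: list[CloneRecord] = []
    next_single = 0
    for i in range(n):
        if is_double[i]:
            # Two independent single-crossover daughter genotypes; which
            # daughter carries the viral tract is independent between arms,
            # so cis and trans are equally likely.
            xl = rng.uniform(0.0, L_left, size=2)
            xr = rng.uniform(0.0, L_right, size=2)
            x = np.where(is_left[None, :], xl[:, None], xr[:, None])
            codes_ab = np.where(dist[None, :] < x, 0, 1)
            parent = np.where(
                codes_ab[0] == codes_ab[1], codes_ab[0], 2
            )  # S where daughters differ
            records.append(
                CloneRecord(
                    clone_id=f"mix{i:05d}",
                    calls=_calls_from_codes(ids, parent),
                    truth_mechanism="DOUBLE_EVENT",
                    subclone_calls=(
                        _calls_from_codes(ids, codes_ab[0]),
                        _calls_from_codes(ids, codes_ab[1]),
                    ),
                )
            )
        else:
            sub = singles[next_single]
            next_single += 1
            sub.clone_id = f"mix{i:05d}"
            records.append(sub)
    return _build_table(
        marker_map, records, f"simulate_double_event_mixture q={q}", params, n
    )


def spell_check_heteroduplex(
    table: CloneTable,
    p_patch: float,
    seed: int = 0,
    p_toward_viral: float = 0.5,
) -> CloneTable:
    """Optional MMR "spell-checking" of heteroduplex tracts before mitosis.

    Each sectored SNP call is independently repaired with probability
    ``p_patch``, collapsing to V with probability ``p_toward_viral`` else
    C.  Hairpin markers are exempt: hairpin loops are refractory to the
    mismatch-recognition machinery.  Off by default — the simulators never
    call this; the observed invariance of retention profiles to MMR status
    argues against tract patching as a default model.
    """
    if not (0.0 <= p_patch <= 1.0) or not (0.0 <= p_toward_viral <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hairpins = {m.id for m in table.map.genotyped_markers if m.kind == "HAIRPIN"}
    patched: list[CloneRecord] = []
    for clone in table.clones:
        calls = dict(clone.calls)
        for mid, call in calls.items():
            if call == "S" and mid not in hairpins and rng.random() < p_patch:
                calls[mid] = "V" if rng.random() < p_toward_viral else "C"
        patched.append(
            CloneRecord(
                clone_id=clone.clone_id,
                calls=calls,
                half_site_present=clone.half_site_present,
                selected=clone.selected,
                truth_mechanism=clone.truth_mechanism,
                parent_id=clone.parent_id,
            )
        )
    return CloneTable(
        map=table.map,
        clones=patched,
        provenance=table.provenance + f" + spell_check(p={p_patch}, seed={seed})",
        meta=dict(table.meta),
    )


def subclone_colony(colony: CloneRecord) -> tuple[CloneRecord, CloneRecord]:
    """Split a COLONY-mode clone into its two daughter subclones.

    Models single-cell subcloning of a sectored colony.  Requires the
    colony record to carry its latent daughter genotypes (i.e. it must come
    from a COLONY-mode simulation, not from disk).
    """
    if colony.subclone_calls is None:
        raise ValueError(
            f"colony {colony.clone_id!r} carries no daughter genotypes; "
            "only COLONY-mode simulated clones can be subcloned"
        )
    a, b = colony.subclone_calls
    return (
        CloneRecord(
            clone_id=f"{colony.clone_id}.a",
            calls=dict(a),
            parent_id=colony.clone_id,
            truth_mechanism=colony.truth_mechanism,
        ),
        CloneRecord(
            clone_id=f"{colony.clone_id}.b",
            calls=dict(b),
            parent_id=colony.clone_id,
            truth_mechanism=colony.truth_mechanism,
        ),
    )
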