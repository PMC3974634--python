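"""Colony sectoring, trans/cis subclone configurations, double-event estimate.

A colony grown in situ from a single targeting event retains unrepaired
heteroduplex DNA: the markers inside the heteroduplex segregate at the
first mitosis, producing a sectored colony whose two cell populations
carry the viral and chromosomal alleles reciprocally.  Because one
ends-out event places heteroduplex on both arms of the same intermediate,
the two subclones of a single-event colony show a *trans* configuration
(the subclone with viral alleles on the left arm has chromosomal alleles
on the right arm).  Colonies founded by two independent events are trans
or cis with equal probability, which turns the observed trans fraction
into an estimator of the double-event contamination.

Single-strand assimilation, by contrast, predicts unsectored colonies:
the non-assimilated daughter lacks the cassette and dies under selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from scipy import stats

from .markers import Arm, CloneRecord, MarkerMap

__all__ = [
    "ConfigurationCall",
    "classify_sectoring",
    "classify_configuration",
    "estimate_double_event_fraction",
    "double_event_interval",
]


@dataclass(frozen=True)
class ConfigurationCall:
    colony_id: str
    call: Literal["TRANS", "CIS", "AMBIGUOUS"]
    # marker_id -> subclone label ("a"/"b") carrying the viral allele,
    # for each parent-sectored marker; empty when AMBIGUOUS early.
    evidence: dict[str, str]
    reason: Optional[str] = None


def classify_sectoring(clone: CloneRecord) -> Literal["SECTORED", "UNSECTORED"]:
    """A colony is sectored iff at least one marker call is S.

    Short heteroduplex tracts falling between two neighbouring markers are
    undetectable, so UNSECTORED does not prove the absence of heteroduplex.
    """
    return "SECTORED" if "S" in clone.calls.values() else "UNSECTORED"


def _sectored_by_arm(parent: CloneRecord, marker_map: MarkerMap) -> dict[Arm, list[str]]:
    out: dict[Arm, list[str]] = {"LEFT": [], "RIGHT": []}
    for m in marker_map.genotyped_markers:
        if parent.calls.get(m.id) == "S":
            out[m.arm].append(m.id)
    return out


def classify_configuration(
    subclone_a: CloneRecord,
    subclone_b: CloneRecord,
    parent: CloneRecord,
    marker_map: MarkerMap,
) -> ConfigurationCall:
    """Classify a both-arm-sectored colony's subclones as TRANS or CIS.

    At every parent-sectored marker the two subclones must be reciprocal
    (one V where the other is C).  Each arm is then assigned to the
    subclone carrying the viral alleles there; TRANS means the two arms
    point to different subclones, CIS the same.  Any failure — a parent
    not sectored on both arms, non-reciprocal subclones, or within-arm
    disagreement about which subclone is viral (possible only with
    genotyping noise) — yields AMBIGUOUS with a reason.
    """
    colony_id = parent.clone_id
    sectored = _sectored_by_arm(parent, marker_map)
    if not sectored["LEFT"] or not sectored["RIGHT"]:
        return ConfigurationCall(
            colony_id,
            "AMBIGUOUS",
            {},
            reason="parent colony is not sectored on both arms",
        )

    evidence: dict[str, str] = {}
    viral_side: dict[Arm, set[str]] = {"LEFT": set(), "RIGHT": set()}
    for arm in ("LEFT", "RIGHT"):
        for mid in sectored[arm]:
            ca, cb = subclone_a.calls.get(mid), subclone_b.calls.get(mid)
            if {ca, cb} != {"V", "C"}:
                return ConfigurationCall(
                    colony_id,
                    "AMBIGUOUS",
                    evidence,
                    reason=(
                        f"subclones not reciprocal at sectored marker {mid!r}: "
                        f"{ca!r} vs {cb!r}"
                    ),
                )
            side = "a" if ca == "V" else "b"
            evidence[mid] = side
            viral_side[arm].add(side)
        if len(viral_side[arm]) != 1:
            return ConfigurationCall(
                colony_id,
                "AMBIGUOUS",
                evidence,
                reason=f"sectored markers on the {arm} arm disagree on the viral subclone",
            )
    (left_side,) = viral_side["LEFT"]
    (right_side,) = viral_side["RIGHT"]
    call = "TRANS" if left_side != right_side else "CIS"
    return ConfigurationCall(colony_id, call, evidence)


def estimate_double_event_fraction(p_trans: float) -> float:
    """Double-event mixture fraction from an observed trans proportion.

    Model: a single-event colony is always TRANS; a colony founded by two
    independent events is TRANS with probability 1/2.  Hence
    ``p_trans = 1 - q/2`` and ``q = 2 (1 - p_trans)``.

    Raises
    ------
    ValueError
        If ``p_trans < 0.5`` (outside the model: even pure double events
        give 50% trans) or ``p_trans > 1``.
    """
    if not (0.5 <= p_trans <= 1.0):
        raise ValueError(
            f"trans proportion {p_trans} outside the model range [0.5, 1]"
        )
    return 2.0 * (1.0 - p_trans)


def double_event_interval(
    n_trans: int, n_total: int, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Point estimate and exact confidence interval for the double-event fraction.

    Propagates a Clopper-Pearson interval on the trans proportion through
    ``q = 2 (1 - p)``, clipping to [0, 1].  Returns ``(q_hat, lo, hi)``.
    """
    if not (0 <= n_trans <= n_total) or n_total == 0:
        raise ValueError("need 0 <= n_trans <= n_total with n_total > 0")
    p_hat = n_trans / n_total
    alpha = 1.0 - confidence
    p_lo = (
        stats.beta.ppf(alpha / 2, n_trans, n_total - n_trans + 1)
        if n_trans > 0
        else 0.0
    )
    p_hi = (
        stats.beta.ppf(1 - alpha / 2, n_trans + 1, n_total - n_trans)
        if n_trans < n_total
        else 1.0
    )
    clip = lambda q: min(1.0, max(0.0, q))
    return clip(2 * (1 - p_hat)), clip(2 * (1 - p_hi)), clip(2 * (1 - p_lo))
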