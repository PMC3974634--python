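"""Domain types for a marked gene-targeting locus.

The system modelled here is a selection cassette (e.g. a NEO resistance
gene replacing an exon of *HPRT*) flanked by two homology arms.  Each arm
carries a handful of vector-specific markers — restriction-site SNPs and
small hairpin insertions — whose per-clone retention or loss reads out
where recombination intermediates were resolved.

Coordinates are 1-based base pairs measured *outward* from the junction of
each arm with the cassette; the cassette itself is treated as a point for
recombination geometry.  A marker on the LEFT arm at distance ``d`` has
signed position ``-d``; on the RIGHT arm, ``+d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

__all__ = [
    "Arm",
    "MarkerKind",
    "Call",
    "Mechanism",
    "CALLS",
    "MECHANISMS",
    "Marker",
    "MarkerMap",
    "Dsb",
    "CloneRecord",
    "CloneTable",
    "SimParams",
    "signed_distance",
    "validate_map",
]

Arm = Literal["LEFT", "RIGHT"]
MarkerKind = Literal["SNP", "HAIRPIN", "HALF_SITE"]

#: Per-marker genotype calls: V = viral allele, C = chromosomal allele,
#: S = sectored (both alleles present in the colony), N = no call.
Call = Literal["V", "C", "S", "N"]
CALLS: tuple[str, ...] = ("V", "C", "S", "N")

Mechanism = Literal[
    "ENDS_OUT_DSBR",
    "SSA_ASSIMILATION",
    "ENDS_IN_DSBR",
    "ENDS_IN_ALT",
    "RANDOM_INTEGRATION",
    "DOUBLE_EVENT",
]
MECHANISMS: tuple[str, ...] = (
    "ENDS_OUT_DSBR",
    "SSA_ASSIMILATION",
    "ENDS_IN_DSBR",
    "ENDS_IN_ALT",
    "RANDOM_INTEGRATION",
    "DOUBLE_EVENT",
)


@dataclass(frozen=True)
class Marker:
    """A single vector-specific marker on one homology arm."""

    id: str
    arm: Arm
    distance: int  # bp from the inner end (cassette junction) of its arm
    kind: MarkerKind = "SNP"

    @property
    def signed_distance(self) -> int:
        return -self.distance if self.arm == "LEFT" else self.distance


@dataclass(frozen=True)
class Dsb:
    """A chromosomal double-strand break at a fixed position on one arm."""

    arm: Arm
    position: int  # bp from the cassette junction, same convention as markers

    @property
    def signed_position(self) -> int:
        return -self.position if self.arm == "LEFT" else self.position


@dataclass
class MarkerMap:
    """Geometry of the marked locus: markers on two arms flanking a cassette."""

    markers: list[Marker]
    arm_length_left: int
    arm_length_right: int
    cassette_id: str = "NEO"

    def arm_length(self, arm: Arm) -> int:
        return self.arm_length_left if arm == "LEFT" else self.arm_length_right

    def get(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(f"unknown marker id: {marker_id!r}")

    def arm_markers(self, arm: Arm) -> list[Marker]:
        return [m for m in self.markers if m.arm == arm]

    @property
    def genotyped_markers(self) -> list[Marker]:
        """SNP and hairpin markers — the ones that receive per-clone calls."""
        return [m for m in self.markers if m.kind != "HALF_SITE"]

    @property
    def half_site(self) -> Optional[Marker]:
        for m in self.markers:
            if m.kind == "HALF_SITE":
                return m
        return None

    def validate(self) -> list[str]:
        return validate_map(self)


def signed_distance(marker_map: MarkerMap, marker_id: str) -> int:
    """Signed bp position of a marker: negative on the LEFT arm, positive on RIGHT.

    Raises
    ------
    KeyError
        If ``marker_id`` is not on the map.
    """
    return marker_map.get(marker_id).signed_distance


def validate_map(marker_map: MarkerMap) -> list[str]:
    """Check map invariants; return a list of human-readable violations.

    An empty list means the map is valid.  The validator never raises.
    """
    violations: list[str] = []
    seen: set[str] = set()
    n_half = 0
    for m in marker_map.markers:
        if m.id in seen:
            violations.append(f"marker {m.id!r}: duplicate id")
        seen.add(m.id)
        if m.arm not in ("LEFT", "RIGHT"):
            violations.append(f"marker {m.id!r}: unknown arm {m.arm!r}")
            continue
        arm_len = marker_map.arm_length(m.arm)
        if not (0 < m.distance <= arm_len):
            violations.append(
                f"marker {m.id!r}: distance {m.distance} outside (0, {arm_len}]"
            )
        if m.kind == "HALF_SITE":
            n_half += 1
    if n_half > 1:
        violations.append(f"map has {n_half} HALF_SITE markers; at most one allowed")
    if marker_map.arm_length_left <= 0:
        violations.append("arm_length_left must be positive")
    if marker_map.arm_length_right <= 0:
        violations.append("arm_length_right must be positive")
    return violations


@dataclass
class CloneRecord:
    """Per-clone marker genotype, as produced by simulation or genotyping.

    ``calls`` covers exactly the SNP/HAIRPIN markers of the associated map.
    ``half_site_present`` records retention of one half of a nuclease
    recognition site knocked into the locus (meaningful only for
    DSB-induced, ends-in experiments).  ``subclone_calls`` carries the two
    daughter genotypes of a colony grown in situ; it is populated by
    COLONY-mode simulation, not persisted to disk.
    """

    clone_id: str
    calls: dict[str, str]
    half_site_present: bool = False
    selected: bool = True
    truth_mechanism: Optional[Mechanism] = None
    parent_id: Optional[str] = None
    subclone_calls: Optional[tuple[dict[str, str], dict[str, str]]] = field(
        default=None, repr=False, compare=False
    )
    #: Latent event geometry (simulation only; never persisted).
    trace: Optional[object] = field(default=None, repr=False, compare=False)


@dataclass
class CloneTable:
    """An ordered collection of clones genotyped against one marker map."""

    map: MarkerMap
    clones: list[CloneRecord]
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clones)

    def validate(self) -> list[str]:
        violations = validate_map(self.map)
        expected = {m.id for m in self.map.genotyped_markers}
        has_half_site = self.map.half_site is not None
        for clone in self.clones:
            got = set(clone.calls)
            missing = expected - got
            extra = got - expected
            if missing:
                violations.append(
                    f"clone {clone.clone_id!r}: missing calls for {sorted(missing)}"
                )
            if extra:
                violations.append(
                    f"clone {clone.clone_id!r}: calls for unknown markers {sorted(extra)}"
                )
            bad = {c for c in clone.calls.values() if c not in CALLS}
            if bad:
                violations.append(
                    f"clone {clone.clone_id!r}: invalid call symbols {sorted(bad)}"
                )
            if clone.half_site_present and not has_half_site:
                violations.append(
                    f"clone {clone.clone_id!r}: half_site_present but map has no HALF_SITE marker"
                )
        return violations


@dataclass
class SimParams:
    """Stochastic-model parameters shared by all mechanism simulators.

    Parameters
    ----------
    n_clones
        Number of accepted (selection-surviving) clones to emit.
    seed
        Seed for the pseudo-random generator; identical seed and params
        give an identical clone table.
    p_alt
        Probability that a DSB-induced ends-in event proceeds by the
        SDSA/HJ-dissolution pathway rather than double-HJ resolution.
        Default 0.17, the minor-pattern fraction observed in vivo.
    dsb
        Chromosomal DSB position; required by the ends-in simulator and
        must be absent for ends-out/assimilation.
    r_reject
        Per-mismatch probability that the mismatch-repair machinery aborts
        a recombination event; an event with ``m`` mismatches survives MMR
        with probability ``(1 - r_reject)**m``.
    host_suppression
        Multiplicative efficiency penalty in an MMR-proficient host
        (MLH1+), applied on top of per-mismatch rejection.  Default 50,
        the reported lower bound of the MLH1 effect.
    n_mismatches
        Total mismatch count ``m`` of the vector/chromosome heteroduplex
        (the original vector carries 15).
    error_rate, missing_rate
        Genotyping-noise probabilities used by the noise injector only;
        mechanism simulators never apply them.
    crossover_law, tract_length
        Joint law of the two per-arm strand crossovers in ends-out
        simulation.  The default IID draws them independently; FIXED_TRACT
        instead places the second crossover ``tract_length`` bp outward
        from the first (clipped at the arm end), modelling a
        constant-length heteroduplex tract.  The marginal retention law of
        a randomly chosen strand differs between the two, which is what
        the linear-gradient analysis discriminates.
    """

    n_clones: int
    seed: int = 0
    p_alt: float = 0.17
    dsb: Optional[Dsb] = None
    r_reject: float = 0.0
    host_suppression: float = 50.0
    host: Literal["DEFICIENT", "PROFICIENT"] = "DEFICIENT"
    n_mismatches: int = 15
    error_rate: float = 0.0
    missing_rate: float = 0.0
    crossover_law: Literal["IID", "FIXED_TRACT"] = "IID"
    tract_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")
        for name in ("p_alt", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.r_reject < 1.0):
            raise ValueError(f"r_reject must be in [0, 1), got {self.r_reject}")
        if self.host_suppression < 1.0:
            raise ValueError("host_suppression must be >= 1")
        if self.n_mismatches < 0:
            raise ValueError("n_mismatches must be >= 0")
        if self.host not in ("DEFICIENT", "PROFICIENT"):
            raise ValueError(f"unknown host status {self.host!r}")
        if self.crossover_law not in ("IID", "FIXED_TRACT"):
            raise ValueError(f"unknown crossover law {self.crossover_law!r}")
        if self.crossover_law == "FIXED_TRACT":
            if self.tract_length is None or self.tract_length <= 0:
                raise ValueError("FIXED_TRACT requires a positive tract_length")

    def validate_against(self, marker_map: MarkerMap) -> None:
        if self.dsb is not None:
            arm_len = marker_map.arm_length(self.dsb.arm)
            if not (0 < self.dsb.position < arm_len):
                raise ValueError(
                    f"DSB position {self.dsb.position} outside (0, {arm_len}) "
                    f"on the {self.dsb.arm} arm"
                )

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)
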