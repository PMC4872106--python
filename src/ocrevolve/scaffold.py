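"""Data model for the Ocr/pocr charge-mimicry scaffold.

Ocr, the product of bacteriophage T7 gene 0.3, is a 116-residue monomer
whose homodimer mimics ~24 bp of bent B-form DNA and inhibits Type I
restriction-modification enzymes.  Each monomer carries 34 acidic residues
(Asp/Glu) and only six basic ones; the acidic side chains trace the
phosphate backbone of the DNA being mimicked.  The fully charge-neutralised
variant pocr replaces every Asp with Asn and every Glu with Gln and is
inactive.

The model here treats the 34 chargeable positions as a binary coordinate
system (acidic vs. neutral) over a fixed scaffold.  Each position belongs to
exactly one of three structural regions mirroring the parts of the Type I
target site:

* ``central``  ("orange") — mimics the non-specific spacer of the target,
* ``specific`` ("green")  — mimics the two sequence-specific half-sites,
* ``flanking`` ("purple") — mimics DNA flanking the recognition sequence.

Two surface loops (loop 1 and loop 2) and the helix-D position 88 are
tracked separately because they carry most of the functionally important
charge.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO

ACIDIC = frozenset("DE")
NEUTRAL_PARTNER = {"D": "N", "E": "Q"}  # isogenic neutral substitutions
ACIDIC_PARTNER = {v: k for k, v in NEUTRAL_PARTNER.items()}
BASIC = frozenset("KR")


class ScaffoldError(ValueError):
    """Raised when a scaffold, region map or clone sequence is invalid."""


class Artifact(enum.Enum):
    """Library artifact class of a clone.

    Anything other than ``INTACT`` is excluded from charge-based
    classification: frameshifted/deleted constructs do not encode the
    scaffold and empty vectors carry no insert at all.
    """

    INTACT = "intact"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    EMPTY_VECTOR = "empty_vector"


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionMap:
    """Assignment of chargeable positions to structural regions.

    ``central``, ``specific`` and ``flanking`` must partition the chargeable
    positions.  ``loop1`` and ``loop2`` are overlays (they sit inside the
    colour regions; canonically loop 2 nests inside ``central`` and loop 1
    inside ``specific``).  ``helixD_88`` is the single toxicity-related
    position (88 on the canonical scaffold).
    """

    central: frozenset[int]
    specific: frozenset[int]
    flanking: frozenset[int]
    loop1: frozenset[int]
    loop2: frozenset[int]
    helixD_88: int = 88

    def __post_init__(self) -> None:
        for a, b in (("central", "specific"), ("central", "flanking"),
                     ("specific", "flanking")):
            overlap = getattr(self, a) & getattr(self, b)
            if overlap:
                raise ScaffoldError(
                    f"regions {a!r} and {b!r} overlap at positions "
                    f"{sorted(overlap)}")
        all_pos = self.all_positions
        for name in ("loop1", "loop2"):
            extra = getattr(self, name) - all_pos
            if extra:
                raise ScaffoldError(
                    f"{name} positions {sorted(extra)} are not chargeable")

    @property
    def all_positions(self) -> frozenset[int]:
        return self.central | self.specific | self.flanking

    def region_of(self, position: int) -> str:
        for name in ("central", "specific", "flanking"):
            if position in getattr(self, name):
                return name
        raise KeyError(position)


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceScaffold:
    """A charge-annotated reference protein (wild-type Ocr or a stand-in).

    ``sequence`` is the fully acidic (wild-type) sequence; derived variants
    are expressed as boolean acidic/neutral vectors over
    ``chargeable_positions`` (1-based, strictly increasing).
    """

    name: str
    sequence: str
    chargeable_positions: tuple[int, ...]
    acidic_identity: Mapping[int, str]
    region_map: RegionMap

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        n = len(seq)
        pos = self.chargeable_positions
        if list(pos) != sorted(set(pos)):
            raise ScaffoldError("chargeable positions must be strictly "
                                "increasing and unique")
        for p in pos:
            if not 1 <= p <= n:
                raise ScaffoldError(
                    f"chargeable position {p} outside 1..{n}")
        acidic_in_seq = {i + 1 for i, aa in enumerate(seq) if aa in ACIDIC}
        declared = set(pos)
        if acidic_in_seq != declared:
            bad = sorted(acidic_in_seq.symmetric_difference(declared))
            raise ScaffoldError(
                "chargeable positions do not match the D/E positions of the "
                f"reference sequence (offending positions: {bad})")
        if set(self.acidic_identity) != declared:
            raise ScaffoldError("acidic_identity must cover exactly the "
                                "chargeable positions")
        for p in pos:
            if self.acidic_identity[p] != seq[p - 1]:
                raise ScaffoldError(
                    f"acidic_identity at {p} ({self.acidic_identity[p]}) "
                    f"disagrees with sequence residue {seq[p - 1]}")
        if self.region_map.all_positions != declared:
            missing = sorted(declared - self.region_map.all_positions)
            extra = sorted(self.region_map.all_positions - declared)
            raise ScaffoldError(
                "region map is not a partition of the chargeable positions "
                f"(missing {missing}, extra {extra})")

    # -- basic facts -------------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_chargeable(self) -> int:
        return len(self.chargeable_positions)

    @property
    def basic_count(self) -> int:
        return sum(1 for aa in self.sequence if aa in BASIC)

    # -- cached index helpers ---------------------------------------------

    @property
    def position_index(self) -> dict[int, int]:
        """Map 1-based position -> index into the acidic vector."""
        return {p: i for i, p in enumerate(self.chargeable_positions)}

    def _region_vector(self, positions: Iterable[int]) -> np.ndarray:
        idx = self.position_index
        v = np.zeros(self.n_chargeable, dtype=bool)
        for p in positions:
            v[idx[p]] = True
        return v

    @property
    def central_vector(self) -> np.ndarray:
        return self._region_vector(self.region_map.central)

    @property
    def specific_vector(self) -> np.ndarray:
        return self._region_vector(self.region_map.specific)

    @property
    def flanking_vector(self) -> np.ndarray:
        return self._region_vector(self.region_map.flanking)

    @property
    def loop1_vector(self) -> np.ndarray:
        return self._region_vector(self.region_map.loop1)

    @property
    def loop2_vector(self) -> np.ndarray:
        return self._region_vector(self.region_map.loop2)

    @property
    def is_aspartate(self) -> np.ndarray:
        """Boolean vector: True where the acidic identity is D (else E)."""
        return np.array([self.acidic_identity[p] == "D"
                         for p in self.chargeable_positions], dtype=bool)

    @property
    def pos88_index(self) -> int | None:
        return self.position_index.get(self.region_map.helixD_88)

    # -- sequence reconstruction ------------------------------------------

    def sequence_for(self, acidic: np.ndarray) -> str:
        """Sequence of the variant with the given acidic/neutral vector."""
        acidic = np.asarray(acidic, dtype=bool)
        if acidic.shape != (self.n_chargeable,):
            raise ScaffoldError(
                f"acidic vector must have length {self.n_chargeable}")
        chars = list(self.sequence)
        for i, p in enumerate(self.chargeable_positions):
            aa = self.acidic_identity[p]
            chars[p - 1] = aa if acidic[i] else NEUTRAL_PARTNER[aa]
        return "".join(chars)

    @property
    def pocr_sequence(self) -> str:
        """The fully neutralised (pocr-like) sequence."""
        return self.sequence_for(np.zeros(self.n_chargeable, dtype=bool))


# ---------------------------------------------------------------------------
# Charge state and profile
# ---------------------------------------------------------------------------


@dataclass
class ChargeState:
    """Acidic/neutral configuration of one clone over the scaffold."""

    scaffold: ReferenceScaffold
    acidic: np.ndarray
    artifact: Artifact = Artifact.INTACT
    clone_id: str = ""

    def __post_init__(self) -> None:
        self.acidic = np.asarray(self.acidic, dtype=bool)
        if self.acidic.shape != (self.scaffold.n_chargeable,):
            raise ScaffoldError(
                f"acidic vector must have length "
                f"{self.scaffold.n_chargeable}, got {self.acidic.shape}")

    @property
    def total(self) -> int:
        return int(self.acidic.sum())

    @property
    def acidic_positions(self) -> tuple[int, ...]:
        return tuple(p for p, a in
                     zip(self.scaffold.chargeable_positions, self.acidic)
                     if a)

    def sequence(self) -> str:
        return self.scaffold.sequence_for(self.acidic)


@dataclass(frozen=True)
class ChargeProfile:
    """Region-resolved acidic-residue counts of an intact clone.

    ``flanking_pct`` is 100 * flanking / total, or None when the clone has
    no acidic residues at all (pocr), in which case every ratio-based rule
    fails closed.
    """

    total: int
    central: int
    specific: int
    flanking: int
    loop1: int
    loop2: int
    pos88_acidic: bool
    flanking_pct: float | None


def charge_state(sequence: str, scaffold: ReferenceScaffold,
                 clone_id: str = "") -> ChargeState:
    """Read the acidic/neutral state of a clone sequence.

    Empty sequences are flagged ``EMPTY_VECTOR``; length mismatches and
    internal stops are flagged ``FRAMESHIFT_DELETION`` (their acidic vector
    is zeroed and ignored downstream).  On an intact clone a residue at a
    chargeable position outside {D, E, N, Q} is an error: the design space
    only toggles the isogenic acidic/neutral pairs.
    """
    seq = sequence.upper().strip()
    zeros = np.zeros(scaffold.n_chargeable, dtype=bool)
    if not seq:
        return ChargeState(scaffold, zeros, Artifact.EMPTY_VECTOR, clone_id)
    if len(seq) != scaffold.length or "*" in seq:
        return ChargeState(scaffold, zeros, Artifact.FRAMESHIFT_DELETION,
                           clone_id)
    acidic = zeros.copy()
    for i, p in enumerate(scaffold.chargeable_positions):
        aa = seq[p - 1]
        if aa in ACIDIC:
            acidic[i] = True
        elif aa in ACIDIC_PARTNER:
            acidic[i] = False
        else:
            raise ScaffoldError(
                f"residue {aa!r} at chargeable position {p} is neither "
                "acidic (D/E) nor its neutral partner (N/Q)")
    return ChargeState(scaffold, acidic, Artifact.INTACT, clone_id)


def charge_profile(state: ChargeState) -> ChargeProfile:
    """Region-resolved charge counts; requires an intact clone."""
    if state.artifact is not Artifact.INTACT:
        raise ScaffoldError(
            f"clone {state.clone_id!r} is {state.artifact.value}; filter "
            "artifact clones before profiling")
    sc = state.scaffold
    a = state.acidic
    total = int(a.sum())
    central = int((a & sc.central_vector).sum())
    specific = int((a & sc.specific_vector).sum())
    flanking = int((a & sc.flanking_vector).sum())
    loop1 = int((a & sc.loop1_vector).sum())
    loop2 = int((a & sc.loop2_vector).sum())
    i88 = sc.pos88_index
    pos88 = bool(a[i88]) if i88 is not None else False
    pct = 100.0 * flanking / total if total > 0 else None
    return ChargeProfile(total=total, central=central, specific=specific,
                         flanking=flanking, loop1=loop1, loop2=loop2,
                         pos88_acidic=pos88, flanking_pct=pct)


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values used for pI computation.

    Defaults are the Bjellqvist values used by the ExPASy compute pI/Mw
    tool.  All values must lie in the open interval (0, 14).
    """

    asp: float = 4.05
    glu: float = 4.45
    cys: float = 9.0
    tyr: float = 10.0
    his: float = 5.98
    lys: float = 10.0
    arg: float = 12.0
    n_term: float = 7.5
    c_term: float = 3.55

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


BJELLQVIST = PkaSet()


@dataclass(frozen=True)
class IonizableComposition:
    """Counts of ionisable groups in a polypeptide."""

    n_asp: int = 0
    n_glu: int = 0
    n_cys: int = 0
    n_tyr: int = 0
    n_his: int = 0
    n_lys: int = 0
    n_arg: int = 0
    n_termini: int = 1
    c_termini: int = 1

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"negative count {name}={v}")

    @classmethod
    def from_sequence(cls, sequence: str) -> "IonizableComposition":
        seq = sequence.upper()
        return cls(n_asp=seq.count("D"), n_glu=seq.count("E"),
                   n_cys=seq.count("C"), n_tyr=seq.count("Y"),
                   n_his=seq.count("H"), n_lys=seq.count("K"),
                   n_arg=seq.count("R"))

    @property
    def n_groups(self) -> int:
        return sum(vars(self).values())


def net_charge(composition: IonizableComposition, pH: float,
               pka: PkaSet = BJELLQVIST) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Each negative group contributes -1/(1 + 10^(pKa - pH)); each positive
    group contributes +1/(1 + 10^(pH - pKa)).  The function is strictly
    decreasing in pH whenever at least one group is present.
    """
    c = composition

    def neg(n: int, pk: float) -> float:
        return -n / (1.0 + 10.0 ** (pk - pH))

    def pos(n: int, pk: float) -> float:
        return n / (1.0 + 10.0 ** (pH - pk))

    return (neg(c.n_asp, pka.asp) + neg(c.n_glu, pka.glu)
            + neg(c.n_cys, pka.cys) + neg(c.n_tyr, pka.tyr)
            + neg(c.c_termini, pka.c_term)
            + pos(c.n_his, pka.his) + pos(c.n_lys, pka.lys)
            + pos(c.n_arg, pka.arg) + pos(c.n_termini, pka.n_term))


def isoelectric_point(composition: IonizableComposition,
                      pka: PkaSet = BJELLQVIST,
                      tol: float = 1e-3) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    Raises if the composition has no ionisable group or if the net charge
    does not change sign inside the bracket (e.g. only basic groups whose
    zero crossing sits above pH 14 would be such a pathology; with termini
    present this does not occur).
    """
    if composition.n_groups == 0:
        raise ValueError("composition has no ionisable group")
    lo, hi = 0.0, 14.0
    f_lo, f_hi = net_charge(composition, lo, pka), net_charge(composition,
                                                              hi, pka)
    if f_lo < 0.0 or f_hi > 0.0:
        raise ValueError("net charge does not cross zero in [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(composition, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def state_composition(state: ChargeState) -> IonizableComposition:
    """Ionisable-group composition of a clone, from its actual sequence."""
    return IonizableComposition.from_sequence(state.sequence())


def state_isoelectric_point(state: ChargeState,
                            pka: PkaSet = BJELLQVIST) -> float:
    return isoelectric_point(state_composition(state), pka)


# ---------------------------------------------------------------------------
# Loading from FASTA + region config
# ---------------------------------------------------------------------------


def _positions(raw: object, what: str) -> frozenset[int]:
    if raw is None:
        return frozenset()
    try:
        return frozenset(int(x) for x in raw)  # type: ignore[union-attr]
    except (TypeError, ValueError) as exc:
        raise ScaffoldError(f"bad position list for {what}: {raw!r}") from exc


def load_region_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def scaffold_from_config(sequence: str, config: Mapping,
                         name: str = "scaffold") -> ReferenceScaffold:
    """Build and validate a scaffold from a sequence plus a region config.

    The config uses keys ``scaffold.length``, ``scaffold.chargeable``,
    ``regions.central/specific/flanking/loop1/loop2`` and ``position88``.
    """
    sc_block = config.get("scaffold", {})
    declared_length = sc_block.get("length")
    seq = sequence.upper()
    if declared_length is not None and declared_length != len(seq):
        raise ScaffoldError(
            f"declared length {declared_length} != sequence length "
            f"{len(seq)}")
    chargeable = tuple(sorted(_positions(sc_block.get("chargeable"),
                                         "scaffold.chargeable")))
    regions = config.get("regions", {})
    region_map = RegionMap(
        central=_positions(regions.get("central"), "regions.central"),
        specific=_positions(regions.get("specific"), "regions.specific"),
        flanking=_positions(regions.get("flanking"), "regions.flanking"),
        loop1=_positions(regions.get("loop1"), "regions.loop1"),
        loop2=_positions(regions.get("loop2"), "regions.loop2"),
        helixD_88=int(config.get("position88", 88)),
    )
    identity = {p: seq[p - 1] for p in chargeable
                if 1 <= p <= len(seq)}
    for p in chargeable:
        if not 1 <= p <= len(seq):
            raise ScaffoldError(
                f"chargeable position {p} outside 1..{len(seq)}")
    return ReferenceScaffold(name=name, sequence=seq,
                             chargeable_positions=chargeable,
                             acidic_identity=identity,
                             region_map=region_map)


def load_scaffold(fasta_path: str | Path,
                  region_config: str | Path) -> ReferenceScaffold:
    """Load a reference scaffold from a protein FASTA and a region config."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ScaffoldError(
            f"expected exactly one record in {fasta_path}, "
            f"found {len(records)}")
    record = records[0]
    config = load_region_config(region_config)
    return scaffold_from_config(str(record.seq), config,
                                name=record.id or "scaffold")


def scaffold_to_config(scaffold: ReferenceScaffold) -> dict:
    """Config dict (round-trippable through YAML) for a scaffold."""
    rm = scaffold.region_map
    return {
        "scaffold": {
            "name": scaffold.name,
            "length": scaffold.length,
            "chargeable": sorted(scaffold.chargeable_positions),
        },
        "regions": {
            "central": sorted(rm.central),
            "specific": sorted(rm.specific),
            "flanking": sorted(rm.flanking),
            "loop1": sorted(rm.loop1),
            "loop2": sorted(rm.loop2),
        },
        "position88": rm.helixD_88,
    }
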