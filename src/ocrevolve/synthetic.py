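"""Synthetic scaffolds, named mutant states and labelled variant sets.

The true Ocr amino-acid sequence is not bundled with the package; every
analysis can instead run on a synthetic 116-residue scaffold that
reproduces the charge architecture of Ocr — 34 chargeable (Asp/Glu)
positions, six basic residues, a 9-position central region containing the
7-position loop 2, a 10-position specific region containing the 5-position
loop 1 and position 88, and 15 flanking positions.  A user-supplied Ocr
FASTA plus region config drops in via :func:`ocrevolve.scaffold.load_scaffold`.

Named fixtures ("M1.9-like" etc.) reproduce the printed charge counts and
region properties of the isolated clones, not their exact residue
positions, which are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .analytics import LABELS, LabelledVariantSet
from .classify import DEFAULT_THRESHOLDS, RuleThresholds, classify_clone
from .scaffold import (ACIDIC, Artifact, ChargeState, ReferenceScaffold,
                       RegionMap, ScaffoldError, load_scaffold)

# Non-ionisable residues used to fill scaffold backbones, so that abstract
# compositions carry no Cys/Tyr/His terms.
_BACKGROUND = "ASTGLVIMFP"


class GenerationError(ValueError):
    """Raised when a synthetic-data request cannot be satisfied."""


def canonical_scaffold() -> ReferenceScaffold:
    """The packaged synthetic Ocr scaffold (116 aa, 34 chargeable).

    Loaded from the shipped FASTA + region config; the region split beyond
    the canonical counts (|central| = 9, |loop1| = 5, |loop2| = 7) is a
    packaged default and can be overridden by loading a custom config.
    """
    data = resources.files("ocrevolve.data")
    with resources.as_file(data / "synthetic_ocr_scaffold.fasta") as fa, \
            resources.as_file(data / "canonical_region_map.yaml") as cfg:
        return load_scaffold(fa, cfg)


def make_abstract_scaffold(length: int = 116, n_chargeable: int = 34,
                           region_sizes: dict[str, int] | None = None,
                           loop1_size: int = 5, loop2_size: int = 7,
                           n_basic: int = 6,
                           seed: int = 0) -> ReferenceScaffold:
    """Random scaffold with the requested charge architecture.

    Chargeable positions are sampled uniformly (no adjacency constraints);
    position 88 is guaranteed chargeable whenever ``n_chargeable > 0`` and
    the scaffold is long enough.  Regions are assigned along the sequence:
    flanking outermost, specific inside, central in the middle, with loop 2
    nested in central and loop 1 in specific.  Deterministic per seed.
    """
    if region_sizes is None:
        if n_chargeable == 34:
            region_sizes = {"central": 9, "specific": 10, "flanking": 15}
        else:
            c = min(n_chargeable, max(0, n_chargeable // 3))
            s = max(0, (n_chargeable - c + 1) // 2)
            region_sizes = {"central": c, "specific": s,
                            "flanking": n_chargeable - c - s}
            loop1_size = min(loop1_size, region_sizes["specific"])
            loop2_size = min(loop2_size, region_sizes["central"])
    c = region_sizes.get("central", 0)
    s = region_sizes.get("specific", 0)
    f = region_sizes.get("flanking", 0)
    if c + s + f != n_chargeable:
        raise GenerationError(
            f"region sizes {region_sizes} do not sum to {n_chargeable}")
    if loop2_size > c:
        raise GenerationError(f"loop2 size {loop2_size} exceeds central "
                              f"size {c}")
    if loop1_size > s:
        raise GenerationError(f"loop1 size {loop1_size} exceeds specific "
                              f"size {s}")
    if n_chargeable + n_basic > length:
        raise GenerationError("scaffold too short for the requested "
                              "chargeable and basic residues")
    rng = np.random.default_rng(seed)
    all_pos = np.arange(1, length + 1)
    if n_chargeable > 0 and 88 <= length:
        others = rng.choice(all_pos[all_pos != 88], size=n_chargeable - 1,
                            replace=False)
        chargeable = np.sort(np.append(others, 88))
    else:
        chargeable = np.sort(rng.choice(all_pos, size=n_chargeable,
                                        replace=False))
    chargeable = tuple(int(p) for p in chargeable)

    # region blocks along the ordered positions: flanking | specific |
    # central | specific | flanking
    mid_lo = (n_chargeable - c) // 2
    central = set(chargeable[mid_lo:mid_lo + c])
    s_left = s // 2
    spec_lo = max(0, mid_lo - s_left)
    specific = set(chargeable[spec_lo:mid_lo])
    specific |= set(chargeable[mid_lo + c:mid_lo + c + (s - len(specific))])
    flanking = set(chargeable) - central - specific
    central_sorted = sorted(central)
    l2_lo = (c - loop2_size) // 2
    loop2 = set(central_sorted[l2_lo:l2_lo + loop2_size])
    loop1 = set(sorted(specific)[:loop1_size])
    region_map = RegionMap(central=frozenset(central),
                           specific=frozenset(specific),
                           flanking=frozenset(flanking),
                           loop1=frozenset(loop1), loop2=frozenset(loop2))

    identity = {p: ("D" if rng.random() < 0.5 else "E") for p in chargeable}
    if 88 in identity:
        identity[88] = "D"  # helix-D aspartate
    non_chargeable = [p for p in range(1, length + 1)
                      if p not in set(chargeable)]
    basic_pos = rng.choice(non_chargeable, size=n_basic, replace=False)
    basic = {int(p): ("K" if i % 2 == 0 else "R")
             for i, p in enumerate(sorted(basic_pos))}
    chars = []
    for p in range(1, length + 1):
        if p in identity:
            chars.append(identity[p])
        elif p in basic:
            chars.append(basic[p])
        else:
            chars.append(_BACKGROUND[p % len(_BACKGROUND)])
    return ReferenceScaffold(name=f"abstract_scaffold_seed{seed}",
                             sequence="".join(chars),
                             chargeable_positions=chargeable,
                             acidic_identity=identity,
                             region_map=region_map)


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------


def _state(scaffold: ReferenceScaffold, positions: set[int],
           clone_id: str) -> ChargeState:
    acidic = np.zeros(scaffold.n_chargeable, dtype=bool)
    idx = scaffold.position_index
    for p in positions:
        acidic[idx[p]] = True
    return ChargeState(scaffold, acidic, Artifact.INTACT, clone_id)


def make_named_fixtures(scaffold: ReferenceScaffold
                        ) -> dict[str, ChargeState]:
    """Reference charge states: wild type, pocr and the isolated clones.

    The "-like" states reproduce the published total mutation counts (16,
    16, 14 and 17 for M2.1, M1.1, M1.9 and M2.8), the loop structure of the
    most informative clones (M2.1 carries all of loop 2 acidic, M2.8 all of
    loop 1) and all pass the activity rule; "3.11-like" passes every charge
    rule but is neutral at position 88 (active yet toxic-risk).
    """
    rm = scaffold.region_map
    if rm.helixD_88 not in scaffold.position_index:
        raise ScaffoldError(
            f"scaffold lacks chargeable position {rm.helixD_88}; named "
            "fixtures require it")
    p88 = rm.helixD_88
    loop1 = sorted(rm.loop1)
    loop2 = sorted(rm.loop2)
    central_extra = sorted(rm.central - rm.loop2)
    flanking = sorted(rm.flanking)
    if len(loop2) < 7 or len(loop1) < 5 or len(flanking) < 6:
        raise ScaffoldError("named fixtures need the canonical region "
                            "sizes (|loop1|=5, |loop2|=7, |flanking|>=6)")

    every = set(scaffold.chargeable_positions)
    fixtures = {
        "wt": _state(scaffold, every, "wt"),
        "pocr": _state(scaffold, set(), "pocr"),
        # total 16: all of loop 2 (7 central) + D88 + 2 loop-1 + 6 flanking
        "M2.1-like": _state(scaffold, set(loop2) | {p88} | set(loop1[:2])
                            | set(flanking[:6]), "M2.1-like"),
        # total 17: all of loop 1 + D88 + 6 of loop 2 + 5 flanking
        "M2.8-like": _state(scaffold, set(loop1) | {p88} | set(loop2[:6])
                            | set(flanking[:5]), "M2.8-like"),
        # total 16: 6 of loop 2 + D88 + 3 loop-1 + 6 flanking
        "M1.1-like": _state(scaffold, set(loop2[:6]) | {p88}
                            | set(loop1[:3]) | set(flanking[:6]),
                            "M1.1-like"),
        # total 14: 6 of loop 2 + D88 + 2 loop-1 + 5 flanking (the minimal
        # active clone)
        "M1.9-like": _state(scaffold, set(loop2[:6]) | {p88}
                            | set(loop1[:2]) | set(flanking[:5]),
                            "M1.9-like"),
        # total 14, charge rules met, position 88 neutral -> toxic risk
        "3.11-like": _state(scaffold, set(loop2[:6]) | set(loop1[:3])
                            | set(flanking[:5]), "3.11-like"),
    }
    for name in ("M2.1-like", "M2.8-like", "M1.1-like", "M1.9-like",
                 "3.11-like"):
        call = classify_clone(fixtures[name])
        if not call.active:
            raise ScaffoldError(
                f"fixture {name} fails the activity rule on this scaffold "
                f"(trace: {call.trace})")
    return fixtures


# ---------------------------------------------------------------------------
# Labelled variant groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Specification of one labelled variant group.

    Region ranges are inclusive (lo, hi) bounds on the acidic count in that
    region; ``None`` leaves the count free.  ``pos88_acidic_prob`` is the
    probability that position 88 is acidic (ignored where a label forces
    it: Toxic groups are always neutral at 88).
    """

    label: str
    count: int
    total_range: tuple[int, int]
    central_range: tuple[int, int] | None = None
    specific_range: tuple[int, int] | None = None
    flanking_range: tuple[int, int] | None = None
    pos88_acidic_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise GenerationError(
                f"label {self.label!r} not in {sorted(LABELS)}")
        if self.count < 0:
            raise GenerationError("count must be >= 0")
        if not 0.0 <= self.pos88_acidic_prob <= 1.0:
            raise GenerationError("pos88_acidic_prob outside [0, 1]")


def _feasible_triples(spec: GroupSpec, sizes: dict[str, int],
                      thresholds: RuleThresholds) -> list[tuple[int, int, int]]:
    """All (central, specific, flanking) triples satisfying the spec (and,
    for Active labels, the activity rule)."""

    def rng_for(name: str, size: int) -> range:
        r = getattr(spec, f"{name}_range")
        lo, hi = (0, size) if r is None else r
        return range(max(lo, 0), min(hi, size) + 1)

    triples = []
    t_lo, t_hi = spec.total_range
    for c in rng_for("central", sizes["central"]):
        for s in rng_for("specific", sizes["specific"]):
            for f in rng_for("flanking", sizes["flanking"]):
                t = c + s + f
                if not t_lo <= t <= t_hi:
                    continue
                if spec.label == "Active":
                    if (t < thresholds.total_min
                            or c < thresholds.central_min
                            or s < thresholds.specific_min
                            or t == 0
                            or 100.0 * f > thresholds.flanking_pct_max * t):
                        continue
                triples.append((c, s, f))
    return triples


def make_variant_groups(specs: list[GroupSpec],
                        scaffold: ReferenceScaffold,
                        seed: int = 0,
                        thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
                        max_tries: int = 500) -> LabelledVariantSet:
    """Generate a labelled variant set with the requested group structure.

    Every generated state is re-validated through the classifier: Active
    entries must pass the activity rule, Inactive entries must fail at
    least one condition, Toxic entries carry a neutral position 88.  The
    partially active labels (PA, PA*) are deliberately unconstrained: no
    printed rule separates them from the other non-active groups, and the
    engineered PA* variants can even sit inside the active charge space.
    """
    rm = scaffold.region_map
    sizes = {"central": len(rm.central), "specific": len(rm.specific),
             "flanking": len(rm.flanking)}
    p88 = rm.helixD_88
    rng = np.random.default_rng(seed)
    entries: list[tuple[ChargeState, str]] = []
    counter = 0
    for spec in specs:
        triples = _feasible_triples(spec, sizes, thresholds)
        if spec.count > 0 and not triples:
            raise GenerationError(
                f"group {spec.label!r}: no (central, specific, flanking) "
                f"combination satisfies total_range={spec.total_range} with "
                "the region constraints")
        for _ in range(spec.count):
            for attempt in range(max_tries):
                c, s, f = triples[rng.integers(len(triples))]
                spec_pool = sorted(rm.specific)
                if spec.label == "Toxic":
                    want88 = False
                elif spec.label == "Active" and p88 in rm.specific:
                    want88 = rng.random() < spec.pos88_acidic_prob
                else:
                    want88 = rng.random() < spec.pos88_acidic_prob
                chosen: set[int] = set()
                if p88 in rm.specific:
                    pool = [p for p in spec_pool if p != p88]
                    if want88 and s >= 1:
                        chosen.add(p88)
                        chosen |= set(rng.choice(pool, size=s - 1,
                                                 replace=False))
                    else:
                        if s > len(pool):
                            continue
                        chosen |= set(rng.choice(pool, size=s,
                                                 replace=False))
                else:
                    chosen |= set(rng.choice(spec_pool, size=s,
                                             replace=False))
                chosen |= set(rng.choice(sorted(rm.central), size=c,
                                         replace=False))
                chosen |= set(rng.choice(sorted(rm.flanking), size=f,
                                         replace=False))
                state = _state(scaffold, chosen,
                               f"{spec.label.lower()}_{counter}")
                call = classify_clone(state, thresholds)
                if spec.label == "Active" and not call.active:
                    continue
                if spec.label == "Inactive" and call.active:
                    continue
                if spec.label == "Toxic" and not call.toxic_risk:
                    continue
                entries.append((state, spec.label))
                counter += 1
                break
            else:
                raise GenerationError(
                    f"group {spec.label!r}: could not draw a state "
                    f"meeting its constraints in {max_tries} tries "
                    f"(total_range={spec.total_range})")
    return LabelledVariantSet(entries=entries,
                              source=f"synthetic(seed={seed})")


def default_group_specs() -> list[GroupSpec]:
    """Group structure emulating the classified ISOR survey: four unique
    actives near the activity boundary plus inactive, partially active and
    toxic groups drawn from the three libraries."""
    return [
        GroupSpec("Active", 4, (14, 17), pos88_acidic_prob=1.0),
        GroupSpec("Inactive", 21, (3, 13)),
        GroupSpec("PA", 15, (6, 13)),
        GroupSpec("PA*", 4, (14, 20)),
        GroupSpec("Toxic", 14, (6, 13), pos88_acidic_prob=0.0),
    ]
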