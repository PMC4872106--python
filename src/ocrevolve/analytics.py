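"""Charge analytics over labelled variant sets and the sequence-space
estimate.

Three analyses mirror how the evolved variant collections are summarised:

* per-group histograms of acidic counts in a region (how many sequences in
  each activity group carry a given number of negative charges there);
* a region-vs-total table — for every variant, its central / specific /
  flanking acidic counts against its total, the coordinate system in which
  the active variants separate from the rest;
* the combinatorial estimate: with 34 two-state positions the design space
  holds 2^34 ≈ 1.7 x 10^10 variants; scaling the observed unique-active
  fraction of the screen up to the full space gives the expected number of
  active sequences and, as log2 of that number, the implied number of
  acidic residues an active variant needs.

Space arithmetic is exact (integers and rationals); logarithms are taken
only at the final step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .scaffold import Artifact, ChargeState, charge_profile

LABELS = ("Active", "PA", "PA*", "Inactive", "Toxic")

_REGION_FIELDS = ("total", "central", "specific", "flanking", "loop1",
                  "loop2")


@dataclass
class LabelledVariantSet:
    """Charge states with external activity labels.

    Labels come from the fixed vocabulary {Active, PA, PA*, Inactive,
    Toxic}; all states must be intact.
    """

    entries: list[tuple[ChargeState, str]]
    source: str = ""

    def __post_init__(self) -> None:
        for state, label in self.entries:
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r} "
                                 f"(expected one of {sorted(LABELS)})")
            if state.artifact is not Artifact.INTACT:
                raise ValueError(
                    f"clone {state.clone_id!r} is {state.artifact.value}; "
                    "labelled sets hold intact states only")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.entries]


def _region_size(state: ChargeState, region: str) -> int:
    sc = state.scaffold
    if region == "total":
        return sc.n_chargeable
    return len(getattr(sc.region_map, region))


def group_histogram(variant_set: LabelledVariantSet,
                    region: str = "total") -> pd.DataFrame:
    """Per-label frequency of acidic counts in a region.

    Rows cover 0..|region|; columns are the labels present in the set (in
    vocabulary order); each column sums to its group size.
    """
    if region not in _REGION_FIELDS:
        raise ValueError(f"unknown region {region!r}; expected one of "
                         f"{_REGION_FIELDS}")
    if not variant_set.entries:
        raise ValueError("variant set is empty")
    size = _region_size(variant_set.entries[0][0], region)
    labels = [lb for lb in LABELS if lb in set(variant_set.labels)]
    table = pd.DataFrame(0, index=pd.RangeIndex(size + 1, name=region),
                         columns=labels, dtype=int)
    for state, label in variant_set.entries:
        profile = charge_profile(state)
        table.loc[getattr(profile, region), label] += 1
    return table


def region_vs_total_table(variant_set: LabelledVariantSet) -> pd.DataFrame:
    """One row per variant: label and region-resolved acidic counts."""
    if not variant_set.entries:
        raise ValueError("variant set is empty")
    rows = []
    for state, label in variant_set.entries:
        p = charge_profile(state)
        rows.append({"clone": state.clone_id, "label": label,
                     "central": p.central, "specific": p.specific,
                     "flanking": p.flanking, "total": p.total})
    return pd.DataFrame(rows)


def boundary_endpoints(scaffold, region: str = "central") -> pd.DataFrame:
    """The two endpoints of the pocr -> wild-type diagonal in the
    region-vs-total plane (exported as rows, not fitted)."""
    size = (scaffold.n_chargeable if region == "total"
            else len(getattr(scaffold.region_map, region)))
    return pd.DataFrame([
        {"clone": "pocr", region: 0, "total": 0},
        {"clone": "wt", region: size, "total": scaffold.n_chargeable},
    ])


# ---------------------------------------------------------------------------
# Sequence-space estimate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpaceEstimate:
    """Extrapolation of the screen's active fraction to the full 2^n space.

    ``active_fraction`` and ``expected_actives`` are exact rationals;
    ``log2_expected`` and ``implied_charges`` (its round-half-even value)
    are None when no actives were observed.
    """

    n_positions: int
    space_size: int
    screened: int
    unique_actives: int
    active_fraction: Fraction
    expected_actives: Fraction
    log2_expected: float | None
    implied_charges: int | None

    @property
    def active_percent(self) -> float:
        return 100.0 * float(self.active_fraction)

    @property
    def active_percent_str(self) -> str:
        """The active fraction as a percentage at one significant figure."""
        return _one_sig_fig_percent(self.active_fraction)


def _one_sig_fig_percent(fraction: Fraction) -> str:
    pct = 100.0 * float(fraction)
    if pct == 0.0:
        return "0%"
    exp = math.floor(math.log10(abs(pct)))
    lead = round(pct / 10.0 ** exp)
    if lead == 10:
        lead, exp = 1, exp + 1
    value = lead * 10.0 ** exp
    decimals = max(0, -exp)
    return f"{value:.{decimals}f}%"


def estimate_space(n_positions: int, screened: int,
                   unique_actives: int) -> SpaceEstimate:
    """Estimate how many of the 2^n_positions variants are active.

    The unique-active fraction of the screen is assumed representative of
    the whole space; ``implied_charges`` = round(log2(expected actives)) is
    then the number of acidic residues that an active variant is expected
    to need (an n-bit space restricted to ~2^k members corresponds to
    fixing ~k positions acidic).
    """
    if screened <= 0:
        raise ValueError("screened must be positive")
    if not 0 <= unique_actives <= screened:
        raise ValueError("unique_actives must lie in [0, screened]")
    if n_positions < 0:
        raise ValueError("n_positions must be >= 0")
    space_size = 2 ** n_positions
    fraction = Fraction(unique_actives, screened)
    expected = space_size * fraction
    if unique_actives == 0:
        log2_expected = None
        implied = None
    else:
        log2_expected = math.log2(expected)
        implied = round(log2_expected)
    return SpaceEstimate(n_positions=n_positions, space_size=space_size,
                         screened=screened, unique_actives=unique_actives,
                         active_fraction=fraction,
                         expected_actives=expected,
                         log2_expected=log2_expected,
                         implied_charges=implied)


# ---------------------------------------------------------------------------
# Plots (optional; matplotlib imported lazily)
# ---------------------------------------------------------------------------


def plot_group_histogram(table: pd.DataFrame, path: str,
                         region: str = "total") -> None:
    """Grouped bar chart of a :func:`group_histogram` table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = table.plot.bar(figsize=(8, 4), width=0.85)
    ax.set_xlabel(f"acidic residues ({region})")
    ax.set_ylabel("sequences")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)


def plot_region_vs_total(table: pd.DataFrame, path: str,
                         region: str = "central",
                         total_min_line: int | None = 14) -> None:
    """Scatter of a region's acidic count against the total, per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in table.groupby("label"):
        ax.scatter(sub["total"], sub[region], label=label, s=25, alpha=0.8)
    if total_min_line is not None:
        ax.axvline(total_min_line, ls="--", c="grey")
    ax.set_xlabel("total acidic residues")
    ax.set_ylabel(f"acidic residues ({region})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
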