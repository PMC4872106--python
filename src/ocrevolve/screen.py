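"""Model of the 2-aminopurine plate selection.

The wet screen plates a restriction-proficient, ClpXP-deficient host on
2AP: the host survives only if the plasmid-borne Ocr variant inhibits the
restriction endonuclease.  Here the plate is abstracted into the boolean
activity rule: a clone is a positive iff its charge profile and pI satisfy
all five activity conditions.  Toxic-risk positives are still recovered by
default (the screen selects for antirestriction, not for host comfort);
``exclude_toxic`` switches that off.

``run_protocol`` chains mutagenesis rounds and screens: every round the
full library — not only positives — seeds the next round, mirroring the
pooling of total DNA between rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import DEFAULT_THRESHOLDS, RuleThresholds
from .isor import Library, RoundParams, SimulationError, simulate_round
from .scaffold import (BJELLQVIST, ChargeState, IonizableComposition,
                       PkaSet, ReferenceScaffold, isoelectric_point)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of screening one library."""

    round_index: int
    screened: int
    positives: int
    unique_actives: int
    positive_states: tuple[ChargeState, ...] = ()
    first_active_round: int | None = None


def _background_composition(scaffold: ReferenceScaffold
                            ) -> IonizableComposition:
    """Ionisable groups contributed by the non-chargeable backbone."""
    return IonizableComposition.from_sequence(scaffold.pocr_sequence)


def pi_table(scaffold: ReferenceScaffold,
             pka: PkaSet = BJELLQVIST) -> np.ndarray:
    """pI lookup by (n acidic D, n acidic E) over the scaffold.

    A clone's ionisable composition depends only on how many D and how many
    E positions are acidic (the backbone is fixed), so screening a library
    needs at most (nD+1) x (nE+1) bisection solves.
    """
    bg = _background_composition(scaffold)
    is_d = scaffold.is_aspartate
    max_d = int(is_d.sum())
    max_e = int((~is_d).sum())
    table = np.empty((max_d + 1, max_e + 1))
    for nd in range(max_d + 1):
        for ne in range(max_e + 1):
            comp = IonizableComposition(
                n_asp=bg.n_asp + nd, n_glu=bg.n_glu + ne,
                n_cys=bg.n_cys, n_tyr=bg.n_tyr, n_his=bg.n_his,
                n_lys=bg.n_lys, n_arg=bg.n_arg)
            table[nd, ne] = isoelectric_point(comp, pka)
    return table


def active_mask(library: Library,
                thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
                pka: PkaSet = BJELLQVIST,
                exclude_toxic: bool = False) -> np.ndarray:
    """Vectorised activity rule over a whole library.

    Equivalent to running :func:`ocrevolve.classify.classify_clone` on each
    clone and reading ``.active`` (artifact clones are never active).
    """
    sc = library.scaffold
    a = library.acidic
    total = a.sum(axis=1)
    central = a[:, sc.central_vector].sum(axis=1)
    specific = a[:, sc.specific_vector].sum(axis=1)
    flanking = a[:, sc.flanking_vector].sum(axis=1)
    n_d = a[:, sc.is_aspartate].sum(axis=1)
    n_e = total - n_d
    pis = pi_table(sc, pka)[n_d, n_e]
    ok = (
        (pis <= thresholds.pi_max)
        & (total >= thresholds.total_min)
        & (central >= thresholds.central_min)
        & (specific >= thresholds.specific_min)
        & (total > 0)
        & (100.0 * flanking <= thresholds.flanking_pct_max * total)
        & library.intact_mask
    )
    if exclude_toxic and thresholds.require_pos88_acidic:
        i88 = sc.pos88_index
        if i88 is not None:
            ok &= a[:, i88]
    return ok


def screen_library(library: Library,
                   thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
                   pka: PkaSet = BJELLQVIST,
                   exclude_toxic: bool = False,
                   keep_states: bool = True) -> SelectionResult:
    """Screen every clone; count positives and distinct positive states."""
    if len(library) == 0:
        raise SimulationError("cannot screen an empty library")
    ok = active_mask(library, thresholds, pka, exclude_toxic)
    positives = int(ok.sum())
    if positives:
        unique = np.unique(library.acidic[ok], axis=0)
        n_unique = unique.shape[0]
        states = tuple(
            ChargeState(library.scaffold, unique[i].copy(),
                        clone_id=f"r{library.round_index}_active{i}")
            for i in range(n_unique)) if keep_states else ()
    else:
        n_unique, states = 0, ()
    return SelectionResult(round_index=library.round_index,
                           screened=len(library), positives=positives,
                           unique_actives=n_unique, positive_states=states)


def run_protocol(rounds: int, clones_per_round: int,
                 params: list[RoundParams] | None = None,
                 thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
                 seed: int | None = None,
                 scaffold: ReferenceScaffold | None = None,
                 pka: PkaSet = BJELLQVIST,
                 exclude_toxic: bool = False) -> list[SelectionResult]:
    """Run the evolve -> screen protocol for the given number of rounds.

    Starts from an all-pocr library, applies one mutagenesis round and one
    screen per round, and always seeds the next round with the full current
    library (total DNA is pooled between rounds).  ``first_active_round``
    on each result is the earliest round, up to that point, with positives.
    """
    from .isor import default_protocol_params

    if rounds < 1:
        raise SimulationError("rounds must be >= 1")
    if scaffold is None:
        from .synthetic import canonical_scaffold
        scaffold = canonical_scaffold()
    if params is None:
        params = default_protocol_params(rounds)
    if len(params) != rounds:
        raise SimulationError(
            f"need {rounds} per-round parameter sets, got {len(params)}")
    rng = np.random.default_rng(seed)
    library = Library.all_pocr(scaffold, clones_per_round)
    results: list[SelectionResult] = []
    first_active: int | None = None
    for r in range(rounds):
        library = simulate_round(library, params[r], rng)
        res = screen_library(library, thresholds, pka, exclude_toxic)
        if first_active is None and res.positives > 0:
            first_active = res.round_index
        results.append(SelectionResult(
            round_index=res.round_index, screened=res.screened,
            positives=res.positives, unique_actives=res.unique_actives,
            positive_states=res.positive_states,
            first_active_round=first_active))
    return results


def first_active_round(results: list[SelectionResult]) -> int | None:
    """Earliest round with at least one positive, or None."""
    for res in results:
        if res.positives > 0:
            return res.round_index
    return None
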