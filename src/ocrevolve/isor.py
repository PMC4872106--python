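"""Stochastic model of ISOR mutagenesis rounds on the pocr scaffold.

ISOR (incorporating synthetic oligonucleotides via gene reassembly) is a
DNA-shuffling method: the gene is fragmented, mixed with mutagenic
oligonucleotides targeting specific codons, and reassembled by PCR.  Here
each round re-introduces acidic codons into the all-neutral pocr gene at a
subset of the 34 chargeable positions.  The model captures:

* the per-round mutation load — each clone receives
  ``k ~ Poisson(mu * neutral / n_chargeable)`` new acidic substitutions,
  truncated at the number of remaining neutral positions.  The thinning by
  ``neutral / n_chargeable`` reflects that oligonucleotides target codons
  regardless of their current state, so hits on already-acidic codons are
  silent; the expected cumulative count after ``r`` rounds then follows
  ``N * (1 - (1 - mu/N)^r)`` with ``N = 34``;
* the four oligonucleotide pools — each round's reactions target four
  disjoint sets of non-contiguous codons; candidate positions are weighted
  to balance picks across pools within a round;
* the adjacency bias — reassembly under-represents consecutively mutated
  codons, so while the bias is active (rounds 1-2 by default) a candidate
  position is down-weighted by ``adjacency_bias`` for every already-acidic
  neighbour (+-1 in the order of chargeable positions).  The final round,
  which uses degenerate oligonucleotides covering successive sites, runs
  without the penalty;
* artifact classes — a configurable fraction of frameshift/deletion
  constructs (default 10 % in the final round) and of empty vectors
  (default 2 % in round 1; empty vectors are lost before the next round).

Substitutions are irreversible (Asn->Asp / Gln->Glu only): a position never
flips back from acidic to neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .scaffold import Artifact, ChargeState, ReferenceScaffold, ScaffoldError

_ARTIFACT_CODE = {Artifact.INTACT: 0, Artifact.FRAMESHIFT_DELETION: 1,
                  Artifact.EMPTY_VECTOR: 2}
_CODE_ARTIFACT = {v: k for k, v in _ARTIFACT_CODE.items()}


class SimulationError(ValueError):
    """Raised on invalid simulator input."""


def default_pools(scaffold: ReferenceScaffold,
                  n_pools: int = 4) -> tuple[frozenset[int], ...]:
    """Interleaved pool partition of the chargeable positions.

    Position ``i`` (in sorted order) goes to pool ``i mod n_pools``, so each
    pool contains only non-contiguous codons — mirroring the design of the
    four separate mutagenesis reactions, whose oligonucleotides must not
    overlap.
    """
    pools: list[set[int]] = [set() for _ in range(n_pools)]
    for i, p in enumerate(scaffold.chargeable_positions):
        pools[i % n_pools].add(p)
    return tuple(frozenset(s) for s in pools)


@dataclass(frozen=True)
class RoundParams:
    """Parameters of one ISOR round.

    ``mean_new_mutations`` is the targeted mutation load per clone per round
    (codons targeted, of which only those still neutral produce a change);
    ``adjacency_bias`` in [0, 1] multiplies a candidate's weight once per
    already-acidic neighbour (1.0 disables the penalty);
    ``frameshift_fraction`` / ``empty_vector_fraction`` are artifact
    probabilities applied after mutagenesis.

    ``cumulative_range``, when set, bounds each clone's cumulative mutation
    count after the round (the Poisson draw is clipped into it).  Oligo
    incorporation is self-limiting — raising the oligonucleotide
    concentration beyond a point inhibits reassembly — so the per-round
    sequenced ranges of the wet libraries serve directly as the support of
    the mutation load when recapitulating the reference protocol.
    """

    mean_new_mutations: float = 4.5
    pools: tuple[frozenset[int], ...] | None = None
    adjacency_bias: float = 0.5
    frameshift_fraction: float = 0.0
    empty_vector_fraction: float = 0.0
    cumulative_range: tuple[int, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_new_mutations < 0:
            raise ValueError("mean_new_mutations must be >= 0")
        if self.cumulative_range is not None:
            lo, hi = self.cumulative_range
            if not 0 <= lo <= hi:
                raise ValueError(
                    f"cumulative_range {self.cumulative_range} invalid")
        if not 0.0 <= self.adjacency_bias <= 1.0:
            raise ValueError("adjacency_bias must lie in [0, 1]")
        for name in ("frameshift_fraction", "empty_vector_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def default_protocol_params(rounds: int = 3) -> list[RoundParams]:
    """Per-round parameters of the three-round reference protocol.

    Round 1 targets a mean of 5 codons (the measured first-round average);
    later rounds use the nominal 4.5 ("four or five").  Cumulative mutation
    loads are calibrated to the sequenced per-round ranges: at most 13
    mutations through round 2 and 8-17 after round 3.  The adjacency
    penalty (0.5) applies in all but the final round; the final round adds
    10 % frameshift/deletion constructs, and round 1 carries 2 % empty
    vectors.
    """
    ranges = {1: (0, 13), 2: (6, 13)}
    params = []
    for r in range(1, rounds + 1):
        params.append(RoundParams(
            mean_new_mutations=5.0 if r == 1 else 4.5,
            adjacency_bias=1.0 if r == rounds else 0.5,
            frameshift_fraction=0.10 if r == rounds else 0.0,
            empty_vector_fraction=0.02 if r == 1 else 0.0,
            cumulative_range=(8, 17) if r == rounds else ranges.get(r,
                                                                    (6, 13)),
        ))
    return params


@dataclass
class Library:
    """A library of clones over one scaffold, stored as a dense matrix.

    ``acidic`` is (n_clones, n_chargeable) boolean; ``artifact`` is a code
    vector (0 intact, 1 frameshift/deletion, 2 empty vector).
    """

    scaffold: ReferenceScaffold
    acidic: np.ndarray
    artifact: np.ndarray
    round_index: int = 0
    params_history: list[RoundParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.acidic = np.asarray(self.acidic, dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=np.uint8)
        n, m = self.acidic.shape
        if m != self.scaffold.n_chargeable:
            raise SimulationError(
                f"acidic matrix has {m} columns, scaffold has "
                f"{self.scaffold.n_chargeable} chargeable positions")
        if self.artifact.shape != (n,):
            raise SimulationError("artifact vector length mismatch")

    def __len__(self) -> int:
        return self.acidic.shape[0]

    @property
    def intact_mask(self) -> np.ndarray:
        return self.artifact == 0

    @property
    def mutation_counts(self) -> np.ndarray:
        return self.acidic.sum(axis=1)

    def clone(self, i: int) -> ChargeState:
        return ChargeState(self.scaffold, self.acidic[i].copy(),
                           _CODE_ARTIFACT[int(self.artifact[i])],
                           clone_id=f"r{self.round_index}_{i}")

    def states(self) -> Iterator[ChargeState]:
        for i in range(len(self)):
            yield self.clone(i)

    @classmethod
    def from_states(cls, states: Sequence[ChargeState],
                    round_index: int = 0) -> "Library":
        if not states:
            raise SimulationError("cannot build a library from zero states")
        scaffold = states[0].scaffold
        for s in states:
            if s.scaffold is not scaffold and (
                    s.scaffold.sequence != scaffold.sequence
                    or s.scaffold.chargeable_positions
                    != scaffold.chargeable_positions):
                raise SimulationError("states come from different scaffolds")
        acidic = np.stack([s.acidic for s in states])
        artifact = np.array([_ARTIFACT_CODE[s.artifact] for s in states],
                            dtype=np.uint8)
        return cls(scaffold, acidic, artifact, round_index)

    @classmethod
    def all_pocr(cls, scaffold: ReferenceScaffold, n: int) -> "Library":
        """Round-0 library: n copies of the fully neutral pocr state."""
        if n <= 0:
            raise SimulationError("library size must be positive")
        return cls(scaffold,
                   np.zeros((n, scaffold.n_chargeable), dtype=bool),
                   np.zeros(n, dtype=np.uint8), round_index=0)


def _pool_index_vector(scaffold: ReferenceScaffold,
                       pools: Sequence[frozenset[int]]) -> np.ndarray:
    """Map each chargeable-position index to its pool id; validates the
    partition."""
    n = scaffold.n_chargeable
    pool_of = np.full(n, -1, dtype=np.int64)
    idx = scaffold.position_index
    for pid, pool in enumerate(pools):
        for p in pool:
            if p not in idx:
                raise SimulationError(
                    f"pool position {p} is not chargeable")
            if pool_of[idx[p]] != -1:
                raise SimulationError(f"position {p} assigned to two pools")
            pool_of[idx[p]] = pid
    if (pool_of == -1).any():
        missing = [scaffold.chargeable_positions[i]
                   for i in np.flatnonzero(pool_of == -1)]
        raise SimulationError(
            f"pools do not cover chargeable positions {missing}")
    return pool_of


def simulate_round(library: Library, params: RoundParams,
                   rng: np.random.Generator | None = None) -> Library:
    """Advance a library by one ISOR round.

    Each output clone derives from a uniformly sampled intact input clone
    (sampling with replacement: the wet protocol pools total DNA).  Empty
    vectors are lost during re-amplification and frameshift constructs do
    not contribute usable template, so neither can parent the next round.
    """
    if rng is None:
        if params.seed is None:
            raise SimulationError(
                "an explicit rng (or RoundParams.seed) is required; runs "
                "must be reproducible")
        rng = np.random.default_rng(params.seed)
    n = len(library)
    if n == 0:
        raise SimulationError("cannot simulate a round on an empty library")
    scaffold = library.scaffold
    m = scaffold.n_chargeable
    pools = params.pools or default_pools(scaffold)
    pool_of = _pool_index_vector(scaffold, pools)
    n_pools = len(pools)

    eligible = np.flatnonzero(library.intact_mask)
    if eligible.size == 0:
        raise SimulationError("no intact clones available as parents")
    parents = eligible[rng.integers(0, eligible.size, size=n)]
    acidic = library.acidic[parents].copy()

    if m > 0:
        parent_total = acidic.sum(axis=1)
        neutral = m - parent_total
        eff_mean = params.mean_new_mutations * neutral / m
        k = rng.poisson(eff_mean)
        if params.cumulative_range is not None:
            lo, hi = params.cumulative_range
            k = np.clip(k, np.maximum(lo - parent_total, 0),
                        np.maximum(hi - parent_total, 0))
        k = np.minimum(k, neutral).astype(np.int64)
        pool_onehot = np.zeros((m, n_pools))
        pool_onehot[np.arange(m), pool_of] = 1.0

        picked_per_pool = np.zeros((n, n_pools))
        kmax = int(k.max()) if k.size else 0
        for step in range(kmax):
            rows = np.flatnonzero(k > step)
            a = acidic[rows]
            # adjacency: number of already-acidic neighbours in position
            # order (previous rounds and this round's picks both count)
            nbr = np.zeros(a.shape, dtype=np.int64)
            nbr[:, 1:] += a[:, :-1]
            nbr[:, :-1] += a[:, 1:]
            w = (~a).astype(float)
            if params.adjacency_bias < 1.0:
                w *= params.adjacency_bias ** nbr
            # pool balance: down-weight pools already used this round
            w *= 1.0 / (1.0 + picked_per_pool[rows][:, pool_of])
            totals = w.sum(axis=1)
            # all-neutral weights cannot vanish: ~a has at least k-step ones
            cum = np.cumsum(w, axis=1)
            u = rng.random(rows.size) * totals
            choice = (cum < u[:, None]).sum(axis=1)
            acidic[rows, choice] = True
            picked_per_pool[rows, pool_of[choice]] += 1.0

    artifact = np.zeros(n, dtype=np.uint8)
    u = rng.random(n)
    artifact[u < params.empty_vector_fraction] = 2
    fs_hi = params.empty_vector_fraction + params.frameshift_fraction
    artifact[(u >= params.empty_vector_fraction) & (u < fs_hi)] = 1

    return Library(scaffold, acidic, artifact,
                   round_index=library.round_index + 1,
                   params_history=list(library.params_history) + [params])


@dataclass(frozen=True)
class MutationStats:
    """Summary of a sequenced sample from a library."""

    n_sampled: int
    n_intact: int
    mean: float
    min: int
    max: int
    histogram: dict[int, int]
    frameshift_fraction: float
    empty_vector_fraction: float


def mutation_count_stats(library: Library, sample_n: int,
                         rng: np.random.Generator) -> MutationStats:
    """Statistics of a random clone sample, mimicking the per-round
    30-clone sequencing check.  Counts are over intact clones only;
    artifacts are reported as fractions of the sample."""
    if sample_n > len(library):
        raise SimulationError(
            f"sample_n={sample_n} exceeds library size {len(library)}")
    idx = rng.choice(len(library), size=sample_n, replace=False)
    art = library.artifact[idx]
    intact = idx[art == 0]
    if intact.size == 0:
        raise SimulationError("sample contains no intact clones")
    counts = library.acidic[intact].sum(axis=1)
    values, freqs = np.unique(counts, return_counts=True)
    return MutationStats(
        n_sampled=sample_n,
        n_intact=int(intact.size),
        mean=float(counts.mean()),
        min=int(counts.min()),
        max=int(counts.max()),
        histogram={int(v): int(f) for v, f in zip(values, freqs)},
        frameshift_fraction=float((art == 1).mean()),
        empty_vector_fraction=float((art == 2).mean()),
    )


def shuffle_pools(sub_libraries: Sequence[Library],
                  rng: np.random.Generator,
                  pools: Sequence[frozenset[int]] | None = None) -> Library:
    """Recombine sub-libraries by uniform crossover over pool boundaries.

    Models the DNase I digestion / PCR reassembly step: each output clone
    takes the block of positions belonging to pool ``p`` from a donor clone
    drawn uniformly from the pooled input.  Output size equals the pooled
    input size.  Only intact clones contribute template.
    """
    if not sub_libraries:
        raise SimulationError("no sub-libraries to shuffle")
    scaffold = sub_libraries[0].scaffold
    for lib in sub_libraries[1:]:
        if (lib.scaffold.sequence != scaffold.sequence
                or lib.scaffold.chargeable_positions
                != scaffold.chargeable_positions):
            raise SimulationError("sub-libraries use different scaffolds")
    pooled = np.concatenate([lib.acidic[lib.intact_mask]
                             for lib in sub_libraries])
    total = sum(len(lib) for lib in sub_libraries)
    if pooled.shape[0] == 0:
        raise SimulationError("no intact clones to shuffle")
    pools = pools or default_pools(scaffold)
    pool_of = _pool_index_vector(scaffold, pools)
    n_pools = len(pools)
    donors = rng.integers(0, pooled.shape[0], size=(total, n_pools))
    out = np.zeros((total, scaffold.n_chargeable), dtype=bool)
    for pid in range(n_pools):
        cols = pool_of == pid
        out[:, cols] = pooled[donors[:, pid]][:, cols]
    round_index = max(lib.round_index for lib in sub_libraries)
    return Library(scaffold, out, np.zeros(total, dtype=np.uint8),
                   round_index=round_index)
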