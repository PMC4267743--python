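"""Back-in-time coalescent simulator with crossover and gene conversion.

Ancestral-recombination-graph bookkeeping in the style of Hudson's ``ms``:
each lineage carries a set of disjoint half-open intervals of [0, L), each
mapped (as a bitmask) to the sample subset it is ancestral to.  Events and
their rates per lineage, with time in coalescent units (pairwise
coalescence rate 1, so the expected height of a sample-of-two tree is 1):

* coalescence of a random pair at total rate k(k-1)/2;
* crossover at rate rho*L/2, with a uniform breakpoint splitting the
  lineage's material into left and right lineages;
* gene conversion at rate gamma*L/2, with a uniform tract start and an
  exponential tract length (mean lam kb), splitting material into
  inside-tract and outside-tract lineages.

Events may fall in non-ancestral material (then they are no-ops) and
empty lineages are pruned, which leaves the sample distribution
unchanged.  Material whose bitmask reaches the full sample is fixed: its
most recent common ancestor has been found, the time is recorded, and the
material is dropped, so the walk terminates at the grand MRCA of every
position.

Rather than storing tree topologies, the simulator accumulates *branch
exposure*: every (interval, sample-subset, duration) triple a lineage
contributed while alive.  Infinite-sites mutations are then dropped as a
Poisson process of rate theta/2 per kb per unit time on that exposure —
a mutation on an exposure segment gives the derived allele to exactly the
samples in its subset, which reproduces mutations on the marginal trees
without ever building them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .data_io import HaplotypeMatrix

__all__ = ["SimConfig", "GenealogySummary", "simulate_genealogy", "drop_mutations", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (rates in ms scaling, lengths in kb).

    ``rate_ratio``, when given, sets ``gamma = rate_ratio * rho`` (the
    conversion-to-crossover rate ratio f).
    """

    n: int
    L: float = 20.0
    theta: float = 1.0
    rho: float = 0.0
    gamma: float = 0.0
    lam: float = 0.0
    seed: int | None = None
    rate_ratio: float | None = None
    max_events: int = 2_000_000

    def __post_init__(self) -> None:
        if self.rate_ratio is not None:
            object.__setattr__(self, "gamma", self.rate_ratio * self.rho)
        if self.n < 2:
            raise ValueError("need sample size n >= 2")
        if self.L <= 0:
            raise ValueError("region length must be positive")
        if min(self.theta, self.rho, self.gamma) < 0:
            raise ValueError("rates must be non-negative")
        if self.gamma > 0 and self.lam <= 0:
            raise ValueError("lam must be positive when gamma > 0")


class SimulationError(RuntimeError):
    pass


# A lineage is (segments, birth_time); segments is a sorted list of
# (left, right, mask) with mask an int bitmask over samples.
Segments = list[tuple[float, float, int]]


@dataclass
class GenealogySummary:
    """Marginal-genealogy summary of one replicate.

    ``exposure`` holds the branch-exposure triples as parallel arrays
    (left, right, duration, mask); ``tmrca_breaks`` / ``tmrca`` give the
    per-position time to the grand MRCA as a step function on [0, L);
    ``tract_lengths`` records every drawn conversion tract length.
    """

    n: int
    L: float
    exposure_left: np.ndarray
    exposure_right: np.ndarray
    exposure_dur: np.ndarray
    exposure_mask: list[int]
    tmrca_breaks: np.ndarray
    tmrca: np.ndarray
    tract_lengths: np.ndarray
    n_events: int

    def tmrca_at(self, x: float) -> float:
        """Height of the marginal tree at position x (coalescent units)."""
        i = bisect.bisect_right(self.tmrca_breaks.tolist(), x) - 1
        return float(self.tmrca[i])

    def n_distinct_trees(self) -> int:
        """Upper bound on distinct marginal trees: TMRCA step count."""
        return len(self.tmrca)


def _split_at(segments: Segments, b: float) -> tuple[Segments, Segments]:
    left: Segments = []
    right: Segments = []
    for l, r, m in segments:
        if r <= b:
            left.append((l, r, m))
        elif l >= b:
            right.append((l, r, m))
        else:
            left.append((l, b, m))
            right.append((b, r, m))
    return left, right


def _split_tract(segments: Segments, a: float, b: float) -> tuple[Segments, Segments]:
    """Material inside [a, b) vs outside."""
    inside: Segments = []
    outside: Segments = []
    for l, r, m in segments:
        il, ir = max(l, a), min(r, b)
        if il < ir:
            inside.append((il, ir, m))
            if l < il:
                outside.append((l, il, m))
            if ir < r:
                outside.append((ir, r, m))
        else:
            outside.append((l, r, m))
    return inside, outside


def _merge(a: Segments, b: Segments, full: int, t: float, tmrca_out: Segments) -> Segments:
    """Union of two segment lists, OR-ing masks where they overlap.

    Segments whose merged mask reaches ``full`` are fixed (MRCA found at
    time ``t``): they are appended to ``tmrca_out`` and dropped.
    """
    points = sorted({p for l, r, _ in a + b for p in (l, r)})
    ia = ib = 0
    merged: Segments = []
    for lo, hi in zip(points[:-1], points[1:]):
        mid = 0.5 * (lo + hi)
        m = 0
        for segs in (a, b):
            for l, r, mm in segs:
                if l <= mid < r:
                    m |= mm
                    break
        if m == 0:
            continue
        if m == full:
            tmrca_out.append((lo, hi, t))  # type: ignore[arg-type]
            continue
        if merged and merged[-1][1] == lo and merged[-1][2] == m:
            merged[-1] = (merged[-1][0], hi, m)
        else:
            merged.append((lo, hi, m))
    return merged


def simulate_genealogy(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenealogySummary:
    """Run the back-in-time walk to the grand MRCA of every position."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.L
    n = cfg.n
    full = (1 << n) - 1
    lineages: list[tuple[Segments, float]] = [
        ([(0.0, L, 1 << i)], 0.0) for i in range(n)
    ]
    exp_l: list[float] = []
    exp_r: list[float] = []
    exp_d: list[float] = []
    exp_m: list[int] = []
    tmrca_segs: Segments = []
    tract_lengths: list[float] = []

    def finalize(idx: int, t: float) -> Segments:
        segs, birth = lineages[idx]
        dt = t - birth
        if dt > 0:
            for l, r, m in segs:
                exp_l.append(l)
                exp_r.append(r)
                exp_d.append(dt)
                exp_m.append(m)
        return segs

    t = 0.0
    n_events = 0
    rec_rate = cfg.rho * L / 2.0
    gc_rate = cfg.gamma * L / 2.0
    while lineages:
        k = len(lineages)
        r_coal = k * (k - 1) / 2.0
        r_rec = k * rec_rate
        r_gc = k * gc_rate
        total = r_coal + r_rec + r_gc
        t += rng.exponential(1.0 / total)
        n_events += 1
        if n_events > cfg.max_events:
            raise SimulationError(
                "event cap exceeded; reduce rho/gamma or the region length"
            )
        u = rng.uniform(0.0, total)
        if u < r_rec:
            i = rng.integers(k)
            b = rng.uniform(0.0, L)
            left, right = _split_at(lineages[i][0], b)
            if left and right:
                finalize(i, t)
                lineages[i] = (left, t)
                lineages.append((right, t))
        elif u < r_rec + r_gc:
            i = rng.integers(k)
            length = rng.exponential(cfg.lam)
            tract_lengths.append(length)
            a = rng.uniform(0.0, L)
            inside, outside = _split_tract(lineages[i][0], a, min(a + length, L))
            if inside and outside:
                finalize(i, t)
                lineages[i] = (inside, t)
                lineages.append((outside, t))
        else:
            i, j = rng.choice(k, size=2, replace=False)
            sa = finalize(i, t)
            sb = finalize(j, t)
            merged = _merge(sa, sb, full, t, tmrca_segs)
            for idx in sorted((int(i), int(j)), reverse=True):
                del lineages[idx]
            if merged:
                lineages.append((merged, t))

    tmrca_segs.sort()
    breaks = [l for l, _, _ in tmrca_segs]
    times = [tt for _, _, tt in tmrca_segs]
    # collapse adjacent equal-time pieces
    cb: list[float] = []
    ct: list[float] = []
    for b_, tt in zip(breaks, times):
        if ct and ct[-1] == tt:
            continue
        cb.append(b_)
        ct.append(tt)
    return GenealogySummary(
        n=n,
        L=L,
        exposure_left=np.array(exp_l),
        exposure_right=np.array(exp_r),
        exposure_dur=np.array(exp_d),
        exposure_mask=exp_m,
        tmrca_breaks=np.array(cb),
        tmrca=np.array(ct),
        tract_lengths=np.array(tract_lengths),
        n_events=n_events,
    )


def drop_mutations(
    summary: GenealogySummary,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> HaplotypeMatrix:
    """Place infinite-sites mutations on the branch exposure.

    The mutation count is Poisson with mean (theta/2) * sum(segment kb *
    duration); each mutation picks an exposure segment proportionally to
    that weight, a uniform position inside it, and marks the segment's
    sample subset as carrying the derived allele.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    weights = (summary.exposure_right - summary.exposure_left) * summary.exposure_dur
    W = float(weights.sum())
    n_mut = int(rng.poisson(cfg.theta / 2.0 * W)) if W > 0 else 0
    if n_mut == 0:
        return HaplotypeMatrix(
            alleles=np.zeros((summary.n, 0), dtype=np.int8),
            positions=np.zeros(0),
            region_length=summary.L,
        )
    idx = rng.choice(weights.size, size=n_mut, p=weights / W)
    pos = rng.uniform(summary.exposure_left[idx], summary.exposure_right[idx])
    order = np.argsort(pos)
    pos = pos[order]
    idx = idx[order]
    # infinite sites: continuous positions are a.s. unique; drop exact ties
    keep = np.concatenate(([True], np.diff(pos) > 0))
    pos, idx = pos[keep], idx[keep]
    alleles = np.zeros((summary.n, pos.size), dtype=np.int8)
    for col, seg_i in enumerate(idx):
        mask = summary.exposure_mask[int(seg_i)]
        for samp in range(summary.n):
            if mask >> samp & 1:
                alleles[samp, col] = 1
    return HaplotypeMatrix(
        alleles=alleles, positions=pos, region_length=summary.L
    )


def simulate_dataset(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypeMatrix:
    """One replicate: genealogy plus mutations, as a haplotype matrix."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    summary = simulate_genealogy(cfg, rng)
    return drop_mutations(summary, cfg, rng)


def simulate_batch(
    cfg: SimConfig, n_reps: int, seed: int | None = None
) -> list[HaplotypeMatrix]:
    """Independent replicates with per-replicate child RNG streams.

    Replicate ``i`` uses the i-th spawn of ``SeedSequence(seed)``, so a
    batch is reproducible and any single replicate can be regenerated.
    """
    if seed is None:
        seed = cfg.seed
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    return [
        simulate_dataset(cfg, np.random.default_rng(s)) for s in streams
    ]
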