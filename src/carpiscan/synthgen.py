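"""Synthetic inputs with known truth for every pipeline stage.

Four generators:

* :func:`bn_genotypes` — independent biallelic sites under the
  Balding-Nichols model, parameterised directly by the differentiation
  parameter F (the expected Weir-Cockerham F_ST).
* :func:`wf_simulate` — a forward Wright-Fisher simulator with population
  splits, continuous migration, a single-generation admixture pulse and an
  optional selective sweep.  Two engines share the model: a count engine
  that iterates exact single-site Wright-Fisher sampling on allele counts
  (valid when sites are unlinked, and fast enough for 10^4-10^5 sites), and
  a haplotype engine with Poisson-crossover recombination for linked panels
  (sweeps, haplotype statistics).
* :func:`annotate_info_fields` — draws GATK-style INFO annotations from a
  passing regime or a designed-to-fail regime so the surviving site set of
  the hard filters is known exactly.
* :func:`simulate_cnv` — Poisson read depth over sliding windows driven by
  known integer copy numbers.

Every generator is bit-reproducible under a fixed seed and returns a
:class:`TruthRecord` describing the generating parameters.

Desk-scale anchors: with a 15-year generation time and a mutation rate of
3.75e-8 per site per year, the per-generation rate is 5.625e-7; a
divergence time of 1.20 My is 80,000 generations, and per-site diversity of
~0.0057 implies an effective size near 2,500 diploids.  The
:func:`carpinus_preset` records these natural parameters; :func:`rescaled`
shrinks any configuration by a factor lambda (sizes and times divided,
rates multiplied) so that theta = 4*N*mu, rho = 4*N*r, 4*N*m and T/N are
preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core_io import VariantTable

#: natural-scale anchors for the study system (per generation / per site)
GENERATION_YEARS = 15.0
MU_PER_YEAR = 3.75e-8
MU_PER_GEN = MU_PER_YEAR * GENERATION_YEARS  # 5.625e-7
SPLIT_YEARS = 1.20e6
SPLIT_GENERATIONS = int(SPLIT_YEARS / GENERATION_YEARS)  # 80,000


@dataclass
class PulseEvent:
    """One-generation admixture pulse: the recipient draws a fraction of its
    parents from the donor population."""

    time_ago: int
    donor: int
    recipient: int
    fraction: float


@dataclass
class SweepConfig:
    """A selective sweep: genic selection (1+s per derived copy) at one site
    in one population, starting ``time_ago`` generations before sampling from
    a single new copy; the run is retried (from the pre-sweep state) until
    the derived frequency at sampling lands in
    [``min_end_freq``, ``max_end_freq``] (an incomplete sweep keeps the core
    polymorphic, where haplotype-length contrasts are strongest)."""

    s: float
    time_ago: int
    pop: int
    site_index: int
    min_end_freq: float = 0.5
    max_end_freq: float = 1.0
    max_tries: int = 200


@dataclass
class DemographyConfig:
    """Split demography for up to four populations plus an outgroup.

    Population 0 continues the ancestral lineage; every other population i
    originates from ``parents[i]`` at ``split_times[i]`` generations before
    sampling.  ``migration[(recipient, donor)]`` is the per-generation
    fraction of the recipient's parents drawn from the donor (active only
    while both exist).  Sizes are diploid.
    """

    sizes: tuple[int, ...]
    split_times: tuple[int, ...]  # entry 0 ignored (ancestral lineage)
    parents: tuple[int, ...]  # entry 0 ignored
    n_anc: int
    mu: float
    L: int
    sample_sizes: tuple[int, ...]
    migration: dict[tuple[int, int], float] = field(default_factory=dict)
    pulse: PulseEvent | None = None
    sweep: SweepConfig | None = None
    r: float = 1e-8  # per bp per generation (haplotype engine only)
    site_spacing: int = 1000  # bp between candidate sites
    burnin_factor: int = 10
    ld_burnin: int | None = None  # linked-phase burn-in gens (default 2*N_anc)
    contig: str = "sim_1"

    def __post_init__(self) -> None:
        k = len(self.sizes)
        if not (len(self.split_times) == len(self.parents) == len(self.sample_sizes) == k):
            raise ValueError("sizes, split_times, parents, sample_sizes must align")
        for m in self.migration.values():
            if not 0 <= m <= 1:
                raise ValueError("migration rates must be in [0, 1]")
        if self.mu < 0 or self.mu > 1:
            raise ValueError("mu must be in [0, 1]")
        for i in range(1, k):
            if self.split_times[i] <= 0:
                raise ValueError("split_times must be positive for populations 1..")
            par = self.parents[i]
            if par != 0 and self.split_times[par] < self.split_times[i]:
                raise ValueError("parent population must predate its child")

    @property
    def n_pops(self) -> int:
        return len(self.sizes)


@dataclass
class TruthRecord:
    """Generating parameters and derived expectations for a synthetic set."""

    kind: str
    params: dict[str, Any]

    def as_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, **self.params}


def carpinus_preset() -> DemographyConfig:
    """Natural-scale two-population split anchored on the study system:
    80,000-generation divergence, mu = 5.625e-7 per generation, N = 2,500
    diploids (theta per site ~ 0.0056).  Use :func:`rescaled` before
    simulating."""
    n = 2500
    return DemographyConfig(
        sizes=(n, n),
        split_times=(0, SPLIT_GENERATIONS),
        parents=(0, 0),
        n_anc=n,
        mu=MU_PER_GEN,
        L=50_000,
        sample_sizes=(13, 8),
    )


def quartet_preset(
    pulse_fraction: float = 0.0,
    n_sites: int = 50_000,
    n: int = 50,
    theta: float = 0.08,
) -> DemographyConfig:
    """Desk-scale four-population ladder ((P1,P2),P3),Outgroup for
    ABBA-BABA work, with an optional recent admixture pulse P3 -> P2.

    Populations of ``n`` diploids split 0.2, 1.0 and 3.0 coalescent units
    (2n generations) before sampling; sample sizes (9, 13, 31, 2) mirror the
    study design (two focal species, a large third population, a small
    pooled outgroup).  Per-site diversity is compressed (theta = 0.08) so
    that 50,000 candidate sites carry roughly the informative-site mass of a
    genome-scale SNP set; the pulse arrives two generations before sampling
    so the admixture fraction is measured before drift erodes it.
    """
    pulse = (
        PulseEvent(time_ago=2, donor=2, recipient=1, fraction=pulse_fraction)
        if pulse_fraction > 0
        else None
    )
    return DemographyConfig(
        sizes=(n, n, n, n),
        split_times=(0, max(1, int(0.2 * 2 * n)), 2 * n, 3 * 2 * n),
        parents=(0, 0, 0, 0),
        n_anc=n,
        mu=theta / (4 * n),
        L=n_sites,
        sample_sizes=(9, 13, 31, 2),
        pulse=pulse,
    )


def sweep_preset(
    with_sweep: bool = True,
    n_sites: int = 10_000,
    n: int = 200,
    contig: str = "sweep_1",
) -> DemographyConfig:
    """Two-population linked-haplotype panel for XP-EHH work, optionally
    carrying a hard sweep centred mid-contig in population 0.

    100-bp candidate-site grid (1 Mb at the default 10,000 sites),
    r = 2e-6 per bp per generation, theta = 4*N*mu = 0.016 after MAF
    filtering leaves a usable column density; the sweep is strong and
    recent (s = 2, 10 generations, conditioned on a final frequency of at
    least 0.9 from a single de-novo copy) so its haplotype footprint is
    window-sized and largely unbroken by recombination or mutation.
    """
    sweep = (
        SweepConfig(s=2.0, time_ago=10, pop=0, site_index=n_sites // 2 + 250,
                    min_end_freq=0.9, max_end_freq=1.0, max_tries=60)
        if with_sweep
        else None
    )
    return DemographyConfig(
        sizes=(n, n),
        split_times=(0, max(20, int(0.2 * 2 * n))),
        parents=(0, 0),
        n_anc=n,
        mu=2e-5,
        r=2e-6,
        L=n_sites,
        site_spacing=100,
        sample_sizes=(13, 9),
        sweep=sweep,
        ld_burnin=100,
        contig=contig,
    )


def neutral_preset(
    n_sites: int = 100_000,
    n: int = 50,
    theta: float = 0.006,
    site_spacing: int = 100,
    sample_size: int = 10,
) -> DemographyConfig:
    """Constant-size neutral single population for calibration work.

    theta = 0.006 matches the per-site diversity scale of the focal species;
    the default grid (100-bp spacing) tiles 200 windows of 50 kb with ~500
    candidate sites each.
    """
    return DemographyConfig(
        sizes=(n,),
        split_times=(0,),
        parents=(0,),
        n_anc=n,
        mu=theta / (4 * n),
        L=n_sites,
        sample_sizes=(sample_size,),
        site_spacing=site_spacing,
    )


def rescaled(config: DemographyConfig, lam: float) -> DemographyConfig:
    """Shrink a demography by lambda: sizes and times divided by lambda,
    mutation/recombination/migration/selection multiplied, preserving
    theta = 4*N*mu, rho = 4*N*r, 4*N*m and T/N."""
    scale_t = lambda t: max(1, int(round(t / lam))) if t > 0 else 0
    sweep = config.sweep
    if sweep is not None:
        sweep = dataclasses.replace(sweep, s=min(1.0, sweep.s * lam), time_ago=scale_t(sweep.time_ago))
    pulse = config.pulse
    if pulse is not None:
        pulse = dataclasses.replace(pulse, time_ago=scale_t(pulse.time_ago))
    return dataclasses.replace(
        config,
        sizes=tuple(max(2, int(round(s / lam))) for s in config.sizes),
        split_times=tuple(scale_t(t) for t in config.split_times),
        n_anc=max(2, int(round(config.n_anc / lam))),
        mu=min(1.0, config.mu * lam),
        r=min(0.5, config.r * lam),
        migration={k: min(1.0, v * lam) for k, v in config.migration.items()},
        pulse=pulse,
        sweep=sweep,
    )


# ---------------------------------------------------------------------------
# Balding-Nichols genotypes
# ---------------------------------------------------------------------------


def bn_genotypes(
    F: float,
    n_pops: int,
    samples_per_pop: int,
    n_sites: int,
    maf_floor: float = 0.05,
    seed: int | None = None,
    site_spacing: int = 1000,
    contig: str = "bn_1",
) -> tuple[VariantTable, TruthRecord]:
    """Independent biallelic genotypes under the Balding-Nichols model.

    Ancestral frequencies are Uniform(maf_floor, 1 - maf_floor); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) and genotypes are
    Binomial(2, p_i).  Sites sit ``site_spacing`` bp apart on one contig so
    window machinery applies directly.
    """
    if not 0 < F < 1:
        raise ValueError("F must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_floor, 1 - maf_floor, size=n_sites)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    pop_freq = rng.beta(a[:, None], b[:, None], size=(n_sites, n_pops))
    n_samples = n_pops * samples_per_pop
    geno = np.empty((n_sites, n_samples, 2), dtype=np.int8)
    for k in range(n_pops):
        cols = slice(k * samples_per_pop, (k + 1) * samples_per_pop)
        alleles = rng.random((n_sites, samples_per_pop, 2)) < pop_freq[:, k, None, None]
        geno[:, cols, :] = alleles.astype(np.int8)
    samples = [f"pop{k + 1}_{i + 1}" for k in range(n_pops) for i in range(samples_per_pop)]
    pos = np.arange(n_sites, dtype=np.int64) * site_spacing
    table = VariantTable(
        contig=np.full(n_sites, contig, dtype=object),
        pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.array([("T",)] * n_sites, dtype=object),
        vclass=np.full(n_sites, "snp", dtype=object),
        qual=np.full(n_sites, np.nan),
        info={},
        genotypes=geno,
        phased=np.zeros((n_sites, n_samples), dtype=bool),
        samples=samples,
    )
    truth = TruthRecord("balding_nichols", {
        "F": F, "n_pops": n_pops, "samples_per_pop": samples_per_pop,
        "n_sites": n_sites, "maf_floor": maf_floor, "seed": seed,
        "ancestral_freq": p, "population_freq": pop_freq,
    })
    return table, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher: count engine (unlinked sites)
# ---------------------------------------------------------------------------


def _wf_counts_generation(
    counts: list[np.ndarray | None],
    sizes: tuple[int, ...],
    active: list[bool],
    mig_in: dict[int, list[tuple[int, float]]],
    mu: float,
    rng: np.random.Generator,
    sel: tuple[int, int, float] | None = None,
) -> None:
    """Advance every active population by one generation, in place.

    For each site the next generation's derived count is Binomial(2N, p')
    with p' the migration-mixed, mutation-adjusted, selection-adjusted
    parental frequency.  Sites that are uniformly lost (or fixed) in the
    population and all its donors are advanced by an exact shortcut: the
    total number of mutant successes over k such sites is Binomial(k*2N, mu)
    and is scattered uniformly — the sum and allocation laws of independent
    binomials make this identical to site-by-site sampling.
    """
    L = None
    freqs = {}
    for i, c in enumerate(counts):
        if active[i] and c is not None:
            freqs[i] = c / (2 * sizes[i])
            L = len(c)
    new_counts: dict[int, np.ndarray] = {}
    for i in list(freqs):
        n2 = 2 * sizes[i]
        p = freqs[i]
        donors = mig_in.get(i, [])
        if donors:
            total_m = sum(m for _, m in donors)
            p_eff = p * (1 - total_m)
            for d, m in donors:
                p_eff = p_eff + m * freqs[d]
        else:
            p_eff = p.copy()
        if sel is not None and sel[0] == i:
            site, s = sel[1], sel[2]
            ps = p_eff[site]
            p_eff[site] = ps * (1 + s) / (1 + s * ps)
        # mutation (symmetric recurrent flips)
        p_eff = p_eff * (1 - mu) + (1 - p_eff) * mu
        # exact shortcut groups: p_eff exactly mu or exactly 1-mu
        lost = p_eff == mu
        fixed = p_eff == 1 - mu
        mid = ~(lost | fixed)
        out = np.empty(L, dtype=np.int64)
        out[mid] = rng.binomial(n2, p_eff[mid])
        for mask, base in ((lost, 0), (fixed, n2)):
            k = int(mask.sum())
            if k == 0:
                continue
            idx = np.flatnonzero(mask)
            out[idx] = base
            hits = rng.binomial(k * n2, mu)
            if hits:
                where = idx[rng.integers(0, k, size=hits)]
                delta = np.bincount(where, minlength=L)[idx]
                if base == 0:
                    out[idx] = np.minimum(delta, n2)
                else:
                    out[idx] = np.maximum(n2 - delta, 0)
        new_counts[i] = out
    for i, c in new_counts.items():
        counts[i] = c


def _sample_unlinked(
    counts: np.ndarray, n2_pop: int, n_dip: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n_dip diploids (2*n_dip gene copies without replacement) from a
    population of allele counts; returns (L, n_dip, 2) int8.  Valid for
    unlinked sites: copies are scattered randomly over haploid slots."""
    L = len(counts)
    k = rng.hypergeometric(counts, n2_pop - counts, 2 * n_dip)
    slots = np.argsort(rng.random((L, 2 * n_dip)), axis=1)
    hap = (slots < k[:, None]).astype(np.int8)
    return hap.reshape(L, n_dip, 2)


def _assemble_table(
    genos: list[np.ndarray],
    pop_names: list[str],
    sample_sizes: tuple[int, ...],
    positions: np.ndarray,
    contig: str,
    phased: bool,
    keep_monomorphic: bool = False,
) -> VariantTable:
    geno = np.concatenate(genos, axis=1)
    samples = [f"{pop_names[k]}_{i + 1}" for k in range(len(sample_sizes)) for i in range(sample_sizes[k])]
    if not keep_monomorphic:
        alt = (geno > 0).sum(axis=(1, 2))
        seg = (alt > 0) & (alt < geno.shape[1] * 2)
        geno = geno[seg]
        positions = positions[seg]
    n_sites = geno.shape[0]
    return VariantTable(
        contig=np.full(n_sites, contig, dtype=object),
        pos=positions.astype(np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.array([("T",)] * n_sites, dtype=object) if n_sites else np.empty(0, dtype=object),
        vclass=np.full(n_sites, "snp", dtype=object),
        qual=np.full(n_sites, np.nan),
        info={},
        genotypes=geno,
        phased=np.full((n_sites, geno.shape[1]), phased, dtype=bool),
        samples=samples,
    )


def _migration_schedule(config: DemographyConfig, alive: list[bool]):
    mig_in: dict[int, list[tuple[int, float]]] = {}
    for (rec, don), m in config.migration.items():
        if m > 0 and alive[rec] and alive[don]:
            mig_in.setdefault(rec, []).append((don, m))
    return mig_in


def wf_simulate(
    config: DemographyConfig,
    seed: int | None = None,
    engine: str = "unlinked",
    pop_names: list[str] | None = None,
    keep_monomorphic: bool = False,
) -> tuple[VariantTable, TruthRecord]:
    """Forward Wright-Fisher simulation of the configured demography.

    ``engine="unlinked"`` iterates exact per-site allele-count sampling
    (sites independent; genotypes at sampling are a random assortment of the
    sampled gene copies) and supports splits, migration, pulses and genic
    selection at one site.  ``engine="linked"`` evolves haplotypes with
    Poisson-crossover recombination and emits fully phased samples; use it
    for haplotype statistics.  Output contains the sites segregating in the
    pooled sample unless ``keep_monomorphic``.
    """
    if engine == "unlinked":
        return _wf_unlinked(config, seed, pop_names, keep_monomorphic)
    if engine == "linked":
        return _wf_linked(config, seed, pop_names, keep_monomorphic)
    raise ValueError("engine must be 'unlinked' or 'linked'")


def _founding_counts(parent_counts: np.ndarray, n2_parent: int, n2_child: int,
                     rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(n2_child, parent_counts / n2_parent)


def _wf_unlinked(config, seed, pop_names, keep_monomorphic):
    rng = np.random.default_rng(seed)
    K = config.n_pops
    pop_names = pop_names or [f"pop{i + 1}" for i in range(K)]
    L = config.L
    mu = config.mu

    # burn-in of the ancestral lineage (population 0 at size n_anc)
    n2a = 2 * config.n_anc
    anc = np.zeros(L, dtype=np.int64)
    burn = config.burnin_factor * config.n_anc
    sizes_b = (config.n_anc,)
    cts: list[np.ndarray | None] = [anc]
    for _ in range(burn):
        _wf_counts_generation(cts, sizes_b, [True], {}, mu, rng)
    anc = cts[0]

    # founding state: population 0 inherits the ancestral lineage (resized)
    counts: list[np.ndarray | None] = [None] * K
    counts[0] = _founding_counts(anc, n2a, 2 * config.sizes[0], rng) \
        if config.sizes[0] != config.n_anc else anc.copy()
    alive = [i == 0 for i in range(K)]

    t_start = max([config.split_times[i] for i in range(1, K)] or [0])
    sweep = config.sweep
    sel = None
    snapshots = None
    tries = 1
    end_freq = float("nan")

    t = t_start
    while t > 0:
        for i in range(1, K):
            if config.split_times[i] == t and not alive[i]:
                par = config.parents[i]
                if not alive[par]:
                    raise ValueError(f"population {i} splits from inactive parent {par}")
                counts[i] = _founding_counts(counts[par], 2 * config.sizes[par], 2 * config.sizes[i], rng)
                alive[i] = True
        mig = _migration_schedule(config, alive)
        if config.pulse is not None and config.pulse.time_ago == t:
            p = config.pulse
            mig = {k: list(v) for k, v in mig.items()}
            mig.setdefault(p.recipient, []).append((p.donor, p.fraction))
        if sweep is not None and sweep.time_ago == t:
            # snapshot state (not the RNG: retries must explore fresh randomness)
            snapshots = ([None if c is None else c.copy() for c in counts], list(alive), t)
            # hard sweep: clear standing variation, introduce exactly one copy
            counts[sweep.pop][sweep.site_index] = 1
            sel = (sweep.pop, sweep.site_index, sweep.s)
        _wf_counts_generation(counts, config.sizes, alive, mig, mu, rng, sel)
        t -= 1
        if sweep is not None and t == 0:
            end_freq = counts[sweep.pop][sweep.site_index] / (2 * config.sizes[sweep.pop])
            if not (sweep.min_end_freq <= end_freq <= sweep.max_end_freq) and tries < sweep.max_tries:
                counts = [None if c is None else c.copy() for c in snapshots[0]]
                alive = list(snapshots[1])
                t = snapshots[2]
                counts[sweep.pop][sweep.site_index] = 1
                tries += 1

    positions = np.arange(L, dtype=np.int64) * config.site_spacing
    genos = []
    for i in range(K):
        if not alive[i]:
            raise ValueError(f"population {i} never became active (check split_times)")
        genos.append(_sample_unlinked(counts[i], 2 * config.sizes[i], config.sample_sizes[i], rng))
    table = _assemble_table(genos, pop_names, config.sample_sizes, positions,
                            config.contig, phased=False, keep_monomorphic=keep_monomorphic)
    truth = TruthRecord("wright_fisher_unlinked", {
        "config": config, "seed": seed, "sweep_tries": tries, "sweep_end_freq": end_freq,
    })
    return table, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher: haplotype engine (linked sites)
# ---------------------------------------------------------------------------

try:  # compiled meiosis kernel; the numpy path below is the reference
    import numba as _nb

    @_nb.njit(cache=True)
    def _meiosis_kernel(pool, par, first, cut_sites, cut_offsets, out, rows):  # pragma: no cover
        L = pool.shape[1]
        for g in range(len(par)):
            h0 = 2 * par[g]
            lo, hi = cut_offsets[g], cut_offsets[g + 1]
            phase = first[g]
            row = rows[g]
            if lo == hi:
                src = h0 + phase
                for j in range(L):
                    out[row, j] = pool[src, j]
                continue
            c = lo
            for j in range(L):
                while c < hi and cut_sites[c] <= j:
                    phase = 1 - phase
                    c += 1
                out[row, j] = pool[h0 + phase, j]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _meiosis_pop(
    H: np.ndarray,
    n_off_dip: int,
    parent_weights: np.ndarray | None,
    positions_bp: np.ndarray,
    r_per_bp: float,
    rng: np.random.Generator,
    donor_H: np.ndarray | None = None,
    donor_prob: float = 0.0,
    donor_weights: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of gametes: (2*n_off_dip, L) from parent haplotypes H
    (2N, L).  Each gamete picks a diploid parent (optionally from a donor
    population with probability ``donor_prob``), and recombines the parent's
    two haplotypes with Poisson(r * span) crossovers."""
    n_gam = 2 * n_off_dip
    L = H.shape[1]
    span = float(positions_bp[-1] - positions_bp[0]) if L > 1 else 0.0

    from_donor = (rng.random(n_gam) < donor_prob) if donor_prob > 0 else np.zeros(n_gam, dtype=bool)

    def pick_parents(k, weights, n_dip):
        if weights is None:
            return rng.integers(0, n_dip, size=k)
        pr = weights / weights.sum()
        return rng.choice(n_dip, size=k, p=pr)

    out = np.empty((n_gam, L), dtype=np.int8)
    for source, mask in ((0, ~from_donor), (1, from_donor)):
        k = int(mask.sum())
        if k == 0:
            continue
        pool = H if source == 0 else donor_H
        w = parent_weights if source == 0 else donor_weights
        par = pick_parents(k, w, pool.shape[0] // 2)
        first = rng.integers(0, 2, size=k)
        ncx = rng.poisson(r_per_bp * span, size=k)
        rows = np.flatnonzero(mask)
        total = int(ncx.sum())
        cut_sites_all = np.searchsorted(
            positions_bp, rng.uniform(positions_bp[0], positions_bp[-1], size=total), side="right"
        )
        cut_offsets = np.zeros(k + 1, dtype=np.int64)
        np.cumsum(ncx, out=cut_offsets[1:])
        cut_sites = np.empty(total, dtype=np.int64)
        for g in range(k):  # per-gamete cut lists must be ascending
            lo, hi = cut_offsets[g], cut_offsets[g + 1]
            if hi > lo:
                cut_sites[lo:hi] = np.sort(cut_sites_all[lo:hi])
        if _HAVE_NUMBA:
            _meiosis_kernel(pool, par.astype(np.int64), first.astype(np.int64),
                            cut_sites, cut_offsets, out, rows.astype(np.int64))
        else:
            plain = ncx == 0
            out[rows[plain]] = pool[2 * par[plain] + first[plain]]
            for i in np.flatnonzero(~plain):
                seg = np.searchsorted(cut_sites[cut_offsets[i]:cut_offsets[i + 1]],
                                      np.arange(L), side="right")
                use_second = (seg + first[i]) % 2
                h0 = pool[2 * par[i]]
                h1 = pool[2 * par[i] + 1]
                out[rows[i]] = np.where(use_second.astype(bool), h1, h0)
    return out


def _mutate(H: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    lam = mu * H.size
    n_mut = rng.poisson(lam)
    if n_mut:
        rows = rng.integers(0, H.shape[0], size=n_mut)
        cols = rng.integers(0, H.shape[1], size=n_mut)
        H[rows, cols] ^= 1


def _wf_linked(config, seed, pop_names, keep_monomorphic):
    rng = np.random.default_rng(seed)
    K = config.n_pops
    pop_names = pop_names or [f"pop{i + 1}" for i in range(K)]
    L = config.L
    positions = np.arange(L, dtype=np.int64) * config.site_spacing
    posf = positions.astype(float)

    def step_pop(H, n_dip, weights=None, donor=None, donor_prob=0.0):
        child = _meiosis_pop(H, n_dip, weights, posf, config.r, rng,
                             donor_H=donor, donor_prob=donor_prob)
        _mutate(child, config.mu, rng)
        return child

    # Ancestral burn-in in two phases: the full burnin_factor * N_anc
    # generations run at the allele-count level (exact per-site Wright-Fisher,
    # cheap), haplotypes are then assigned at linkage equilibrium, and a
    # final linked phase of ~2 * N_anc generations builds the LD structure.
    # Pairwise LD at distance d equilibrates within ~min(2N, 1/(2 r d))
    # generations, so haplotype statistics at the scales recombination can
    # reach are at stationarity while total burn-in cost stays linear.
    n2a = 2 * config.n_anc
    cts: list[np.ndarray | None] = [np.zeros(L, dtype=np.int64)]
    ld_gens = config.ld_burnin if config.ld_burnin is not None else 2 * config.n_anc
    ld_gens = min(ld_gens, config.burnin_factor * config.n_anc)
    for _ in range(config.burnin_factor * config.n_anc - ld_gens):
        _wf_counts_generation(cts, (config.n_anc,), [True], {}, config.mu, rng)
    H_anc = (rng.random((n2a, L)) < (cts[0] / n2a)[None, :]).astype(np.int8)
    for _ in range(ld_gens):
        H_anc = step_pop(H_anc, config.n_anc)

    pops: list[np.ndarray | None] = [None] * K
    pops[0] = step_pop(H_anc, config.sizes[0])
    alive = [i == 0 for i in range(K)]

    sweep = config.sweep
    sel_pop = None
    snapshot = None
    tries = 1
    end_freq = float("nan")

    t = max([config.split_times[i] for i in range(1, K)] or [0])
    t_start = t
    while t > 0:
        for i in range(1, K):
            if config.split_times[i] == t and not alive[i]:
                par = config.parents[i]
                pops[i] = step_pop(pops[par], config.sizes[i])
                alive[i] = True
        if sweep is not None and sweep.time_ago == t:
            snapshot = ([None if h is None else h.copy() for h in pops], list(alive), t)
            # hard sweep: clear standing variation, introduce exactly one copy
            pops[sweep.pop][:, sweep.site_index] = 0
            row = rng.integers(0, pops[sweep.pop].shape[0])
            pops[sweep.pop][row, sweep.site_index] = 1
            sel_pop = sweep.pop
        new_pops: list[np.ndarray | None] = [None] * K
        mig = _migration_schedule(config, alive)
        pulse = config.pulse if (config.pulse is not None and config.pulse.time_ago == t) else None
        for i in range(K):
            if not alive[i]:
                continue
            weights = None
            if sel_pop == i and sweep is not None:
                dosage = pops[i][:, sweep.site_index].reshape(-1, 2).sum(axis=1)
                weights = (1.0 + sweep.s) ** dosage
            donor, dprob = None, 0.0
            donors = mig.get(i, [])
            if pulse is not None and pulse.recipient == i and alive[pulse.donor]:
                donors = donors + [(pulse.donor, pulse.fraction)]
            if donors:
                # single strongest donor per generation keeps the pool swap simple
                dpop, dprob = max(donors, key=lambda x: x[1])
                donor = pops[dpop]
            new_pops[i] = step_pop(pops[i], config.sizes[i], weights, donor, dprob)
        for i in range(K):
            if new_pops[i] is not None:
                pops[i] = new_pops[i]
        t -= 1
        if sweep is not None and t == 0:
            end_freq = pops[sweep.pop][:, sweep.site_index].mean()
            if not (sweep.min_end_freq <= end_freq <= sweep.max_end_freq) and tries < sweep.max_tries:
                pops = [None if h is None else h.copy() for h in snapshot[0]]
                alive = list(snapshot[1])
                t = snapshot[2]
                pops[sweep.pop][:, sweep.site_index] = 0
                row = rng.integers(0, pops[sweep.pop].shape[0])
                pops[sweep.pop][row, sweep.site_index] = 1
                tries += 1

    genos = []
    for i in range(K):
        if not alive[i]:
            raise ValueError(f"population {i} never became active (check split_times)")
        pick = rng.choice(config.sizes[i], size=config.sample_sizes[i], replace=False)
        hap_rows = np.stack([2 * pick, 2 * pick + 1], axis=1).reshape(-1)
        sampled = pops[i][hap_rows].T  # (L, 2*n_dip)
        genos.append(sampled.reshape(L, config.sample_sizes[i], 2))
    table = _assemble_table(genos, pop_names, config.sample_sizes, positions,
                            config.contig, phased=True, keep_monomorphic=keep_monomorphic)
    truth = TruthRecord("wright_fisher_linked", {
        "config": config, "seed": seed, "sweep_tries": tries, "sweep_end_freq": float(end_freq),
        "sweep_position": None if sweep is None else int(positions[sweep.site_index]),
        "t_start": t_start,
    })
    return table, truth


# ---------------------------------------------------------------------------
# INFO-field fixture for the hard filters
# ---------------------------------------------------------------------------

#: passing-regime draws keep every annotation strictly on the safe side of
#: its SNP hard-filter threshold; the fail regime pushes one named clause over
_PASS_RANGES = {
    "QD": (5.0, 35.0),
    "FS": (0.0, 30.0),
    "ReadPosRankSum": (-4.0, 4.0),
    "MQ": (45.0, 60.0),
    "MQRankSum": (-4.0, 4.0),
    "SOR": (0.2, 2.0),
}
_FAIL_RANGES = {
    "QD": (0.0, 1.99),
    "FS": (60.01, 300.0),
    "ReadPosRankSum": (-15.0, -8.01),
    "MQ": (10.0, 39.99),
    "MQRankSum": (-20.0, -12.51),
    "SOR": (3.01, 6.0),
}


def annotate_info_fields(
    table: VariantTable, clean_fraction: float = 0.7, seed: int | None = None
) -> tuple[VariantTable, TruthRecord]:
    """Attach GATK-style INFO annotations drawn from two labelled regimes.

    Each site is independently "clean" with probability ``clean_fraction``
    (all six annotations drawn safely inside the SNP hard-filter thresholds)
    or assigned one failing clause, cycled so every clause is exercised.  The
    truth record carries the per-site expected-pass flags and failing clause
    names, so the surviving count of the hard filters is known exactly.
    """
    rng = np.random.default_rng(seed)
    n = table.n_sites
    clean = rng.random(n) < clean_fraction
    keys = list(_PASS_RANGES)
    info = {k: rng.uniform(*_PASS_RANGES[k], size=n) for k in keys}
    fail_clause = np.full(n, "", dtype=object)
    fail_idx = np.flatnonzero(~clean)
    for j, site in enumerate(fail_idx):
        k = keys[j % len(keys)]
        info[k][site] = rng.uniform(*_FAIL_RANGES[k])
        fail_clause[site] = k
    new = dataclasses.replace(table, info={k: v for k, v in info.items()})
    truth = TruthRecord("info_annotation", {
        "clean_fraction": clean_fraction, "seed": seed,
        "expected_pass": clean, "failing_clause": fail_clause,
        "n_expected_survivors": int(clean.sum()),
    })
    return new, truth


# ---------------------------------------------------------------------------
# CNV depths
# ---------------------------------------------------------------------------


def simulate_cnv(
    n_genes: int,
    frac_differentiated: float,
    pop_means: tuple[float, float] = (2.0, 4.0),
    noise_sd: float = 0.7,
    depth_per_copy: float = 15.0,
    samples_per_pop: tuple[int, int] = (13, 8),
    window: int = 10_000,
    step: int = 2_000,
    gene_length: int = 30_000,
    gene_gap: int = 20_000,
    ploidy: int = 2,
    read_length: int = 100,
    seed: int | None = None,
    contig: str = "cnv_1",
):
    """Poisson read depth over sliding windows driven by known copy numbers.

    Genes are tiled on one synthetic contig; a fraction of them is
    differentiated (population mean copy numbers ``pop_means``), the rest sit
    at the ploidy baseline in both populations.  Per sample the true gene CN
    is the population mean plus rounded Normal(0, noise_sd), floored at 0.
    The per-base copy number equals the gene CN inside genes and the ploidy
    elsewhere; a window's true CN is its per-base mean, so windows straddling
    a gene edge carry a mixture.  Window depth is
    Poisson(depth_per_copy * CN/2 * window_len) / window_len.
    Window depth is Poisson-distributed over reads
    (depth_per_copy * CN/2 * window_len / read_length expected reads).
    Returns (DepthMatrix, GeneTable, PopulationMap, TruthRecord); the truth
    carries both the real-valued window CN and its rounded integer version.
    """
    from .core_io import DepthMatrix, GeneTable, PopulationMap, make_windows

    rng = np.random.default_rng(seed)
    na, nb = samples_per_pop
    samples = [f"monb_{i + 1}" for i in range(na)] + [f"moll_{i + 1}" for i in range(nb)]
    popmap = PopulationMap({s: ("popA" if i < na else "popB") for i, s in enumerate(samples)})

    pitch = gene_length + gene_gap
    starts = np.arange(n_genes, dtype=np.int64) * pitch + gene_gap // 2
    genes = GeneTable(
        gene_id=np.array([f"g{i + 1:04d}" for i in range(n_genes)], dtype=object),
        contig=np.full(n_genes, contig, dtype=object),
        start=starts,
        end=starts + gene_length,
    )
    n_diff = int(round(frac_differentiated * n_genes))
    differentiated = np.zeros(n_genes, dtype=bool)
    differentiated[rng.choice(n_genes, size=n_diff, replace=False)] = True

    true_cn = np.empty((n_genes, na + nb), dtype=int)
    for g in range(n_genes):
        means = pop_means if differentiated[g] else (float(ploidy), float(ploidy))
        mus = np.array([means[0]] * na + [means[1]] * nb)
        cn = np.rint(mus + rng.normal(0, noise_sd, size=na + nb)).astype(int)
        true_cn[g] = np.maximum(cn, 0)

    contig_len = int(n_genes * pitch + gene_gap)
    windows = make_windows({contig: contig_len}, window, step)
    lens = windows.end - windows.start
    # per-base CN mixture: gene CN over the overlap, ploidy over the rest
    win_cn = np.full((len(windows), na + nb), float(ploidy))
    for g in range(n_genes):
        ov = np.minimum(windows.end, genes.end[g]) - np.maximum(windows.start, genes.start[g])
        hit = np.flatnonzero(ov > 0)
        frac = ov[hit] / lens[hit]
        win_cn[hit] += frac[:, None] * (true_cn[g][None, :] - ploidy)

    # Poisson on reads, not read-bases: a window at depth d holds
    # ~d * len / read_length reads, which sets the realistic noise floor
    lam_reads = depth_per_copy * win_cn / 2.0 * lens[:, None] / read_length
    depth = rng.poisson(lam_reads) * read_length / lens[:, None]
    import pandas as pd

    dm = DepthMatrix(windows, pd.DataFrame(depth, columns=samples))
    truth = TruthRecord("cnv", {
        "n_genes": n_genes, "frac_differentiated": frac_differentiated,
        "pop_means": pop_means, "noise_sd": noise_sd, "depth_per_copy": depth_per_copy,
        "seed": seed, "differentiated": differentiated, "true_gene_cn": true_cn,
        "true_window_cn": win_cn, "true_window_cn_int": np.rint(win_cn).astype(int),
        "samples": samples,
    })
    return dm, genes, popmap, truth
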