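"""Forward-in-time colony simulator.

Generates every input the pipeline consumes: homozygous founder panels
with a controllable divergence, colonies bred for G discrete generations
under idealized breeder schemes (random pair mating, circular ring
mating, rotational group mating, and IGS-style periodic re-introgression
from a small reservoir), diploid genotypes with per-allele error and
missingness, full mosaic/pedigree truth, quantitative phenotypes with a
planted QTL of stated variance share plus covariates, and
reduced-representation variant tables.

Meiosis uses Poisson crossovers without interference on a uniform genetic
map — the same map model the mosaic HMM assumes — so parameter-recovery
tests are internally consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    ColonyPanel,
    FounderPanel,
    GenotypeMatrix,
    MarkerMap,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

SCHEMES = ("random", "circular", "rotational", "igs_bottleneck")


@dataclass
class SimConfig:
    n_founders: int = 8
    divergence: float = 0.3          # target mean pairwise founder difference
    n_markers: int = 351
    region_span_bp: int = 10_000_000
    chromosome: str = "1"
    scheme: str = "random"
    generations: int = 30
    census_size: int = 100
    n_groups: int = 4                # rotational scheme groups
    reservoir_size: int = 8          # IGS reservoir census
    igs_fraction: float = 0.5        # parents replaced from reservoir per generation
    mutation_rate: float = 0.0       # per allele per generation
    genotype_error: float = 0.0
    missing_rate: float = 0.0
    cM_per_Mb: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in ("divergence", "mutation_rate", "genotype_error", "missing_rate",
                     "igs_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.census_size < 2 or self.generations < 1 or self.n_founders < 2:
            raise ValueError("need census_size >= 2, generations >= 1, founders >= 2")


@dataclass
class SimTruth:
    founder_labels: np.ndarray       # n x 2 x m founder index per haplotype per marker
    pedigree: list[np.ndarray]       # per generation: n x 2 parent indices
    founder_fractions: np.ndarray    # length-weighted true per-founder fractions
    qtl_marker: int | None = None
    qtl_effects: np.ndarray | None = None
    het_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))
    offspring_counts: list[np.ndarray] = field(default_factory=list)
    pre_error_dosages: np.ndarray | None = None


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> MarkerMap:
    pos = np.sort(rng.choice(np.arange(1, cfg.region_span_bp), cfg.n_markers, replace=False))
    df = pd.DataFrame(
        {
            "marker_id": [f"m{k:05d}" for k in range(cfg.n_markers)],
            "chromosome": cfg.chromosome,
            "position_bp": pos.astype(np.int64),
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return MarkerMap(df)


def simulate_founders(
    S: int,
    n_markers: int,
    divergence: float,
    seed: int = 0,
    markers: MarkerMap | None = None,
    region_span_bp: int = 10_000_000,
) -> FounderPanel:
    """Homozygous founder haplotypes with target mean pairwise difference.

    For divergence d <= 0.5, per-marker allele frequencies across founders
    are Beta(a, a) with a = d / (1 - 2d), which makes the expected pairwise
    difference 2 E[p(1-p)] = d.  d > 0.5 is only attainable with two
    founders (anti-correlated alleles): markers differ with probability d.
    """
    rng = np.random.default_rng(seed)
    if markers is None:
        markers = _marker_map(
            SimConfig(n_founders=S, n_markers=n_markers, region_span_bp=region_span_bp),
            rng,
        )
    m = len(markers)
    if divergence == 0:
        hap = np.repeat(rng.integers(0, 2, size=(1, m)), S, axis=0)
    elif divergence <= 0.5:
        a = divergence / (1 - 2 * divergence) if divergence < 0.5 else None
        p = rng.beta(a, a, size=m) if a is not None else np.full(m, 0.5)
        hap = (rng.random((S, m)) < p).astype(np.int8)
    else:
        if S != 2:
            raise ValueError("divergence > 0.5 requires exactly 2 founders")
        base = rng.integers(0, 2, size=m).astype(np.int8)
        flip = rng.random(m) < divergence
        hap = np.vstack([base, np.where(flip, 1 - base, base)])
    names = [f"F{k}" for k in range(S)]
    calls = (2 * hap).astype(np.int8)
    return FounderPanel(GenotypeMatrix(names, markers, calls))


def _gamete(
    alleles: np.ndarray, labels: np.ndarray, pos_cm: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete from a parent's two (allele, label) haplotypes.

    Poisson crossovers, no interference, uniform map given marker genetic
    positions ``pos_cm``.
    """
    length = pos_cm[-1] - pos_cm[0]
    n_x = rng.poisson(length / 100.0)
    start = rng.integers(0, 2)
    if n_x == 0:
        return alleles[start].copy(), labels[start].copy()
    cuts = np.sort(rng.uniform(pos_cm[0], pos_cm[-1], size=n_x))
    phase = (start + np.searchsorted(cuts, pos_cm, side="right")) % 2
    idx = np.arange(alleles.shape[1])
    return alleles[phase, idx].copy(), labels[phase, idx].copy()


def _expected_het(hap_alleles: np.ndarray) -> float:
    """Mean 2pq over markers for a population's gamete pool."""
    p = hap_alleles.reshape(-1, hap_alleles.shape[-1]).mean(axis=0)
    return float(np.mean(2 * p * (1 - p)))


def _mate_pairs(
    scheme: str,
    N: int,
    gen: int,
    n_groups: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """N x 2 parent indices for the next generation under a scheme."""
    if scheme in ("random", "igs_bottleneck"):
        p1 = rng.integers(0, N, size=N)
        shift = rng.integers(1, N, size=N)
        p2 = (p1 + shift) % N  # distinct partner
        return np.column_stack([p1, p2])
    if scheme == "circular":
        # ring-neighbour mating: offspring i from parents (i, i+1 mod N)
        i = np.arange(N)
        return np.column_stack([i, (i + 1) % N])
    if scheme == "rotational":
        # sires of group k mate dams of group (k + gen) mod n_groups
        groups = np.array_split(np.arange(N), n_groups)
        pairs = []
        for k in range(n_groups):
            sires = groups[k]
            dams = groups[(k + 1 + gen) % n_groups]
            for i in range(len(groups[k])):
                pairs.append((sires[i % len(sires)], dams[rng.integers(0, len(dams))]))
        return np.asarray(pairs[:N])
    raise ValueError(scheme)


def breed_colony(
    founders: FounderPanel, cfg: SimConfig, colony_id: str = "sim"
) -> tuple[ColonyPanel, SimTruth]:
    """Breed a colony forward for ``cfg.generations`` generations.

    Generation 0 assigns founder haplotypes cyclically (balanced founder
    representation).  Each generation draws parent pairs per the scheme and
    every offspring receives one recombinant gamete from each parent.
    Genotypes are emitted with per-allele error and missingness; the truth
    object records haplotype founder labels, pedigree, heterozygosity
    trajectory, and realized gamete counts per parent.
    """
    rng = np.random.default_rng(cfg.seed)
    mmap = founders.genotypes.markers
    m = len(mmap)
    S = founders.n_founders
    founder_hap = (founders.genotypes.calls == 2).astype(np.int8)  # S x m
    pos_cm = mmap.positions_bp * cfg.cM_per_Mb / 1e6

    N = cfg.census_size
    if N % 2:
        N += 1
        logger.warning("census size adjusted to even: %d", N)
    # generation 0: haplotypes drawn cyclically from founders
    alleles = np.empty((N, 2, m), dtype=np.int8)
    labels = np.empty((N, 2, m), dtype=np.int16)
    k = 0
    for i in range(N):
        for h in range(2):
            alleles[i, h] = founder_hap[k % S]
            labels[i, h] = k % S
            k += 1

    if cfg.scheme == "igs_bottleneck":
        R = max(cfg.reservoir_size, 2)
        res_alleles = np.empty((R, 2, m), dtype=np.int8)
        res_labels = np.empty((R, 2, m), dtype=np.int16)
        k = 0
        for i in range(R):
            for h in range(2):
                res_alleles[i, h] = founder_hap[k % S]
                res_labels[i, h] = k % S
                k += 1

    pedigree: list[np.ndarray] = []
    het_traj = [_expected_het(alleles)]
    offspring_counts: list[np.ndarray] = []
    for gen in range(cfg.generations):
        if cfg.scheme == "igs_bottleneck":
            # breed the reservoir randomly at its own (small) census
            rpairs = _mate_pairs("random", R, gen, cfg.n_groups, rng)
            new_ra = np.empty_like(res_alleles)
            new_rl = np.empty_like(res_labels)
            for i, (pa, pb) in enumerate(rpairs):
                new_ra[i, 0], new_rl[i, 0] = _gamete(res_alleles[pa], res_labels[pa], pos_cm, rng)
                new_ra[i, 1], new_rl[i, 1] = _gamete(res_alleles[pb], res_labels[pb], pos_cm, rng)
            res_alleles, res_labels = new_ra, new_rl
            # replace a fraction of colony parents with reservoir animals
            n_rep = int(round(cfg.igs_fraction * N))
            if n_rep:
                take = rng.integers(0, R, size=n_rep)
                put = rng.choice(N, size=n_rep, replace=False)
                alleles[put] = res_alleles[take]
                labels[put] = res_labels[take]
        pairs = _mate_pairs(cfg.scheme, N, gen, cfg.n_groups, rng)
        pedigree.append(pairs)
        counts = np.bincount(pairs.ravel(), minlength=N)
        offspring_counts.append(counts)
        new_a = np.empty_like(alleles)
        new_l = np.empty_like(labels)
        for i, (pa, pb) in enumerate(pairs):
            new_a[i, 0], new_l[i, 0] = _gamete(alleles[pa], labels[pa], pos_cm, rng)
            new_a[i, 1], new_l[i, 1] = _gamete(alleles[pb], labels[pb], pos_cm, rng)
        alleles, labels = new_a, new_l
        if cfg.mutation_rate > 0:
            mut = rng.random(alleles.shape) < cfg.mutation_rate
            alleles = np.where(mut, 1 - alleles, alleles).astype(np.int8)
        het_traj.append(_expected_het(alleles))

    dosage = alleles.sum(axis=1).astype(np.int8)  # pre-error
    calls = dosage.copy()
    if cfg.genotype_error > 0:
        flips = rng.random((N, 2, m)) < cfg.genotype_error
        noisy = np.where(flips, 1 - alleles, alleles)
        calls = noisy.sum(axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    samples = [f"{colony_id}_i{i:04d}" for i in range(N)]
    g = GenotypeMatrix(samples, mmap, calls)
    scheme_meta = {"igs_bottleneck": "igs", "random": "random", "circular": "circular",
                   "rotational": "rotational"}[cfg.scheme]
    colony = ColonyPanel(colony_id, g, breeding_scheme=scheme_meta, colony_size=N)

    w = _weights_bp(mmap)
    frac = np.zeros(S)
    for s in range(S):
        frac[s] = ((labels == s) * w[None, None, :]).sum()
    frac /= frac.sum()
    truth = SimTruth(
        founder_labels=labels,
        pedigree=pedigree,
        founder_fractions=frac,
        het_trajectory=np.asarray(het_traj),
        offspring_counts=offspring_counts,
        pre_error_dosages=dosage,
    )
    return colony, truth


def _weights_bp(markers: MarkerMap) -> np.ndarray:
    pos = markers.positions_bp.astype(float)
    n = len(markers)
    w = np.zeros(n)
    for i in range(n):
        left = pos[i] - pos[i - 1] if i > 0 else 0.0
        right = pos[i + 1] - pos[i] if i < n - 1 else 0.0
        w[i] = (left + right) / 2.0
    return w


def effective_size_from_offspring(counts: np.ndarray) -> float:
    """Ne from realized gamete counts (monoecious, discrete generations):
    Ne = (N k_bar - 2) / (k_bar - 1 + Var(k) / k_bar)."""
    N = len(counts)
    kbar = counts.mean()
    vk = counts.var()
    return (N * kbar - 2) / (kbar - 1 + vk / kbar)


def plant_phenotype(
    colony: ColonyPanel,
    truth: SimTruth,
    target_variance: float,
    effect_type: str = "marker_additive",
    qtl_marker: int | None = None,
    founder_effects: np.ndarray | None = None,
    covariates: dict[str, float] | None = None,
    seed: int = 0,
) -> PhenotypeTable:
    """Quantitative trait with a planted QTL explaining ``target_variance``
    of the phenotypic variance.

    ``marker_additive`` uses the (pre-error) dosage at ``qtl_marker``;
    ``founder_allele`` assigns per-founder haplotype effects (drawn N(0,1)
    unless given), enabling shared- vs colony-specific-effect designs.
    ``covariates`` maps covariate name to its variance share; each is a
    balanced two-level factor.  Residual noise is Gaussian.
    """
    if not 0 <= target_variance <= 0.9:
        raise ValueError("target_variance must be in [0, 0.9]")
    rng = np.random.default_rng(seed)
    g = colony.genotypes
    n = g.n_samples
    m = g.n_markers
    if qtl_marker is None:
        # default: the most central clearly polymorphic marker
        dos = (
            truth.pre_error_dosages if truth.pre_error_dosages is not None else g.calls
        ).astype(float)
        sd = dos.std(axis=0)
        ok = np.flatnonzero(sd >= max(0.3, np.quantile(sd, 0.5)))
        qtl_marker = int(ok[np.argmin(np.abs(ok - m // 2))]) if len(ok) else m // 2
    if effect_type == "marker_additive":
        dos = (
            truth.pre_error_dosages[:, qtl_marker]
            if truth.pre_error_dosages is not None
            else g.calls[:, qtl_marker]
        ).astype(float)
        gvalue = dos
    elif effect_type == "founder_allele":
        if founder_effects is None:
            S = int(truth.founder_labels.max()) + 1
            founder_effects = rng.standard_normal(S)
        lab = truth.founder_labels[:, :, qtl_marker]
        gvalue = founder_effects[lab].sum(axis=1)
    else:
        raise ValueError(f"unknown effect_type {effect_type!r}")

    y = np.zeros(n)
    data = {}
    var_left = 1.0 - target_variance
    if target_variance > 0:
        sd = gvalue.std()
        if sd == 0:
            logger.warning("planted QTL is monomorphic; trait carries no genetic signal")
        else:
            y += np.sqrt(target_variance) * (gvalue - gvalue.mean()) / sd
    for name, share in (covariates or {}).items():
        lv = rng.integers(0, 2, size=n)
        data[name] = np.where(lv == 1, "b", "a")
        y += np.sqrt(share) * (lv - lv.mean()) / max(lv.std(), 1e-12)
        var_left -= share
    if var_left < 0:
        raise ValueError("variance shares exceed 1")
    y += np.sqrt(var_left) * rng.standard_normal(n)
    truth.qtl_marker = qtl_marker
    truth.qtl_effects = founder_effects if effect_type == "founder_allele" else None
    df = pd.DataFrame({"trait": y, **data}, index=pd.Index(g.samples, name="sample_id"))
    df["colony"] = colony.colony_id
    return PhenotypeTable(df)


def simulate_variant_table(
    colony: ColonyPanel,
    catalogue: set[tuple[str, int, str]],
    novel_fraction: float,
    n_calls: int = 1000,
    mean_depth: float = 20.0,
    read_length: int = 100,
    site_dist_range: tuple[int, int] = (0, 64),
    seed: int = 0,
) -> pd.DataFrame:
    """Reduced-representation style variant-call table.

    Calls are drawn from the catalogue except for a ``novel_fraction``
    share placed at positions absent from it; depths are Poisson, read-end
    and restriction-site distances uniform in their configured ranges.
    """
    if not 0 <= novel_fraction <= 1:
        raise ValueError("novel_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cat = sorted(catalogue)
    known_pos = {(c, p) for c, p, _ in catalogue}
    rows = []
    chrom = colony.genotypes.markers.chromosomes[0]
    for _ in range(n_calls):
        if cat and rng.random() >= novel_fraction:
            c, p, alt = cat[rng.integers(0, len(cat))]
        else:
            while True:
                p = int(rng.integers(1, 200_000_000))
                if (chrom, p) not in known_pos:
                    break
            c = chrom
            alt = "ACGT"[rng.integers(0, 4)]
        rows.append(
            (
                c,
                p,
                "N",
                alt,
                int(rng.poisson(mean_depth)),
                int(rng.integers(0, read_length // 2 + 1)),
                int(rng.integers(site_dist_range[0], site_dist_range[1] + 1)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "position_bp",
            "ref",
            "alt",
            "depth",
            "dist_to_read_end_bp",
            "dist_to_restriction_site_bp",
        ],
    )


def subsample_markers(
    dense: ColonyPanel,
    n_markers: int = 351,
    n_regions: int = 4,
    n_reps: int = 1000,
    seed: int = 0,
    sparse_metrics=None,
):
    """Sparse-panel validation by repeated marker subsampling.

    Draws ``n_reps`` samples of ``n_markers`` markers from ``n_regions``
    span-matched windows of the dense map, recomputes colony metrics for
    each, and (when a sparse-panel ColonyMetrics is supplied) reports the
    percentile position of each sparse estimate within the replicate
    distribution.
    """
    from .metrics import ColonyMetrics, colony_metrics

    rng = np.random.default_rng(seed)
    g = dense.genotypes
    M = g.n_markers
    if M < n_markers:
        raise ValueError("dense set smaller than requested subsample")
    # split the map into span-matched windows; sample markers evenly
    bounds = np.linspace(0, M, n_regions + 1).astype(int)
    per_region = np.diff(np.linspace(0, n_markers, n_regions + 1).astype(int))
    reps: list[ColonyMetrics] = []
    for _ in range(n_reps):
        chosen: list[int] = []
        for r in range(n_regions):
            pool = np.arange(bounds[r], bounds[r + 1])
            chosen.extend(rng.choice(pool, size=min(per_region[r], len(pool)), replace=False))
        sub = ColonyPanel(
            dense.colony_id,
            g.subset_markers(sorted(chosen)),
            breeding_scheme=dense.breeding_scheme,
        )
        reps.append(colony_metrics(sub))
    out = {"replicates": reps}
    if sparse_metrics is not None:
        pct = {}
        for attr in ("mean_maf", "mean_het", "mean_inbreeding_coef_pct"):
            vals = np.array([getattr(r, attr) for r in reps])
            pct[attr] = float(np.mean(vals <= getattr(sparse_metrics, attr)) * 100)
        out["percentiles"] = pct
    return out
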