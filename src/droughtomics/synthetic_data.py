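"""Synthetic genotype / phenotype / expression generators.

The generators emulate the structure of a replicated multi-environment
oilseed-rape variety trial: ~119 varieties genotyped at ~29k biallelic SNPs
on 19 chromosomes (A01–A10, C01–C09), ~7 subpopulations, block-structured
linkage disequilibrium decaying on the 100 kbp–1 Mbp scale, 12 traits scored
in year × watering-regime environments with 3 replicates, and
negative-binomial expression counts with differentially expressed genes
planted near quantitative trait nucleotides (QTNs).

Every generator is deterministic given its seed and returns truth objects
(QTN lists, per-environment heritability, DEG labels) beside the data so
that downstream estimators can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1  # sentinel dosage for a missing genotype call, used pipeline-wide

#: chromosome names of the B. napus A and C subgenomes
CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 11)) + tuple(
    f"C{i:02d}" for i in range(1, 10)
)


def default_chrom_lengths() -> dict[str, int]:
    """Subgenome-proportioned chromosome lengths (A ≈ 284 Mbp, C ≈ 489 Mbp)."""
    lengths = {c: 28_400_000 for c in CHROMOSOMES if c.startswith("A")}
    lengths.update({c: 54_300_000 for c in CHROMOSOMES if c.startswith("C")})
    return lengths


@dataclass
class SimConfig:
    """Genotype-simulation settings.

    The defaults are the trial's conditions: 119 varieties, 29,310 SNPs over
    19 chromosomes, seven subpopulations at moderate differentiation, and LD
    decaying at the few-hundred-kbp scale.
    """

    n_samples: int = 119
    chrom_lengths: dict[str, int] = field(default_factory=default_chrom_lengths)
    n_snps: int = 29_310
    n_subpops: int = 7
    fst: float = 0.10
    ld_block_len: int = 2_100_000
    #: per-bp decorrelation rate of the latent haplotype process; together
    #: with ld_block_len (and the default seven-subpopulation structure,
    #: which adds long-range admixture LD) the defaults put the fitted
    #: genome-wide LD-decay distance near the study scale of ~288 kbp
    recomb_rate: float = 3.1e-7
    maf_floor: float = 0.05
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not (0 < self.maf_floor <= 0.5):
            raise ValueError(f"maf_floor must be in (0, 0.5], got {self.maf_floor}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        unknown = set(self.chrom_lengths) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"unknown chromosome names: {sorted(unknown)}")
        if self.n_samples < 2 or self.n_snps < 1 or self.n_subpops < 1:
            raise ValueError("n_samples, n_snps and n_subpops must be positive")


@dataclass
class GenotypeMatrix:
    """Samples × SNPs dosage matrix with a per-SNP map.

    ``dosage`` holds alt-allele counts 0/1/2 with :data:`MISSING` for no-calls.
    ``snps`` has columns id, chrom, pos (1-based), ref, alt.
    ``subpop`` (optional truth) is the simulated subpopulation per sample.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray
    subpop: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        return d

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing calls."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosage=self.dosage[:, np.asarray(mask)],
            subpop=self.subpop,
        )


def _allocate_positions(
    chrom_lengths: dict[str, int], n_snps: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Scatter n_snps across chromosomes proportionally to length."""
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the largest chromosomes
    for i in np.argsort(-lengths)[: n_snps - counts.sum()]:
        counts[i] += 1
    rows = []
    for chrom, length, k in zip(chroms, lengths, counts):
        if k > length:
            raise ValueError(
                f"cannot place {k} SNPs on chromosome {chrom} of length {int(length)}"
            )
        pos = np.sort(rng.choice(int(length), size=k, replace=False)) + 1
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(rows, ignore_index=True)
    snps.insert(0, "id", snps["chrom"] + "_" + snps["pos"].astype(str))
    return snps


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate biallelic dosages with population structure and block LD.

    Subpopulation allele frequencies follow the Balding–Nichols model
    around ancestral frequencies drawn uniformly on
    [maf_floor, 1 − maf_floor].  Haplotypes are built from a latent
    Gaussian AR(1) copula: within an ``ld_block_len`` block the latent
    correlation between adjacent SNPs is exp(−recomb_rate·distance) and
    blocks are independent, so pairwise r² declines with distance at the
    configured scale.  Missing calls are injected uniformly at
    ``missing_rate``.  Sampling noise can push observed MAF below
    ``maf_floor``; the QC stage is responsible for re-filtering.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    snps = _allocate_positions(cfg.chrom_lengths, cfg.n_snps, rng)
    m = len(snps)

    p_anc = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=m)
    if cfg.fst > 0 and cfg.n_subpops > 1:
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
        p_sub = rng.beta(a, b, size=(cfg.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-4, 1.0 - 1e-4)
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

    subpop = rng.integers(cfg.n_subpops, size=cfg.n_samples)
    thresholds = stats.norm.ppf(p_sub)  # allele carried iff latent z < ppf(p)

    n_hap = 2 * cfg.n_samples
    hap_subpop = np.repeat(subpop, 2)
    geno = np.zeros((cfg.n_samples, m), dtype=np.int8)

    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[idx]
        block = pos // cfg.ld_block_len
        z = np.empty((n_hap, len(idx)))
        z[:, 0] = rng.standard_normal(n_hap)
        eps = rng.standard_normal((n_hap, len(idx)))
        for k in range(1, len(idx)):
            if block[k] != block[k - 1]:
                rho = 0.0
            else:
                rho = np.exp(-cfg.recomb_rate * (pos[k] - pos[k - 1]))
            z[:, k] = rho * z[:, k - 1] + np.sqrt(1.0 - rho * rho) * eps[:, k]
        alleles = (z < thresholds[hap_subpop][:, idx]).astype(np.int8)
        geno[:, idx] = alleles[0::2] + alleles[1::2]

    if cfg.missing_rate > 0:
        mask = rng.random((cfg.n_samples, m)) < cfg.missing_rate
        geno[mask] = MISSING

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(4, size=m)]
    offset = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + offset) % 4]
    snps["ref"] = ref
    snps["alt"] = alt

    samples = [f"G{i + 1}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples=samples, snps=snps, dosage=geno, subpop=subpop)


def expected_allelic_r2(rho: float, p1: float, p2: float) -> float:
    """Squared allelic correlation implied by the latent copula.

    Alleles are thresholded Gaussians, so their correlation is attenuated
    relative to the latent correlation ρ:
    r = (Φ₂(z₁, z₂; ρ) − p₁p₂)/√(p₁q₁p₂q₂) with zᵢ = Φ⁻¹(pᵢ).
    """
    if rho <= 0:
        return 0.0
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal.cdf(
        [z1, z2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    r = (p11 - p1 * p2) / denom
    return float(r * r)


def expected_r2_curve(cfg: SimConfig, distances: np.ndarray, n_grid: int = 8) -> np.ndarray:
    """Population expectation of pairwise r² at the given distances.

    Averages the attenuated copula r² over independent allele-frequency
    draws (midpoint grid on [maf_floor, 1 − maf_floor]) and multiplies by
    the probability that a pair at distance d shares an LD block
    (≈ max(0, 1 − d/ld_block_len)).  Finite-sample noise (≈1/n at
    independence) is not included.
    """
    qs = (np.arange(n_grid) + 0.5) / n_grid
    freqs = cfg.maf_floor + qs * (1.0 - 2.0 * cfg.maf_floor)
    out = np.empty(len(distances))
    for k, d in enumerate(distances):
        rho = np.exp(-cfg.recomb_rate * d)
        same = max(0.0, 1.0 - d / cfg.ld_block_len)
        if same == 0.0 or rho <= 0.0:
            out[k] = 0.0
            continue
        acc = 0.0
        for pa in freqs:
            for pb in freqs:
                acc += expected_allelic_r2(rho, pa, pb)
        out[k] = same * acc / (n_grid * n_grid)
    return out


def expected_half_decay(cfg: SimConfig) -> float:
    """Distance at which the expected r² curve falls to half its 1-bp value."""
    from scipy.optimize import brentq

    top = expected_r2_curve(cfg, np.array([1.0]))[0]

    def f(d: float) -> float:
        return expected_r2_curve(cfg, np.array([d]))[0] - top / 2.0

    hi = float(cfg.ld_block_len)
    return float(brentq(f, 1.0, hi))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    ``qtn_positions`` are (chrom, pos) pairs that must exist in the genotype
    matrix; ``qtn_effects`` are additive effects per alt allele in trait
    units.  ``h2_target`` is the broad-sense heritability the polygenic
    component is scaled to realise per environment.  ``env_effects`` maps an
    environment label "WW17"-style (regime+2-digit year) or (year, regime)
    tuple to the environment mean.
    """

    trait: str
    qtn_positions: list[tuple[str, int]] = field(default_factory=list)
    qtn_effects: list[float] = field(default_factory=list)
    h2_target: float = 0.6
    env_effects: dict = field(default_factory=dict)
    gxe_sd: float = 0.0
    rep_sd: float = 0.0
    residual_sd: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError(f"h2_target must be in [0, 1], got {self.h2_target}")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if len(self.qtn_positions) != len(self.qtn_effects):
            raise ValueError("qtn_positions and qtn_effects differ in length")


def env_label(year: int, regime: str) -> str:
    """Compact environment code, e.g. (2017, 'WW') → 'WW17'."""
    return f"{regime}{year % 100:02d}"


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: list[TraitArchitecture],
    envs: list[tuple[int, str]],
    n_reps: int = 3,
    seed: int = 0,
):
    """Simulate the replicated trial phenotype table.

    Each observation is

        y = μ_env + Σ dosage·effect + u_poly + gxe + rep_effect + ε

    with the polygenic value ``u_poly`` scaled so that the realised
    per-environment broad-sense heritability (genotypic variance over
    genotypic-plus-residual variance) approximates ``h2_target``.

    Returns ``(pheno, truth)`` where ``pheno`` is a long-format DataFrame
    with columns variety, trait, year, regime, rep, value and ``truth`` maps
    trait → dict with the QTN list, per-environment true heritability and
    the per-variety genetic values.
    """
    rng = np.random.default_rng(seed)
    snp_index = {
        (c, p): j
        for j, (c, p) in enumerate(zip(geno.snps["chrom"], geno.snps["pos"]))
    }
    d = geno.dosage_float()
    # mean-impute missing dosages for the generative genetic value
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)

    records = []
    truth: dict[str, dict] = {}
    for a in arch:
        a.validate()
        qtn_idx = []
        for chrom, pos in a.qtn_positions:
            if (chrom, pos) not in snp_index:
                raise ValueError(f"QTN {chrom}:{pos} not present in genotype matrix")
            qtn_idx.append(snp_index[(chrom, pos)])
        effects = np.asarray(a.qtn_effects, dtype=float)
        g_qtn = d[:, qtn_idx] @ effects if qtn_idx else np.zeros(geno.n_samples)

        v_qtn = float(np.var(g_qtn))
        v_err = a.residual_sd**2
        h2 = a.h2_target
        if h2 >= 1.0:
            h2 = 1.0 - 1e-9
        v_gen_needed = h2 / (1.0 - h2) * v_err
        v_poly = max(v_gen_needed - v_qtn - a.gxe_sd**2, 0.0)
        u_poly = rng.normal(0.0, np.sqrt(v_poly), size=geno.n_samples)

        v_gen = v_qtn + v_poly + a.gxe_sd**2
        true_h2 = v_gen / (v_gen + v_err) if (v_gen + v_err) > 0 else 0.0

        env_h2 = {}
        for year, regime in envs:
            label = env_label(year, regime)
            mu = a.env_effects.get(label, a.env_effects.get((year, regime), 0.0))
            gxe = (
                rng.normal(0.0, a.gxe_sd, size=geno.n_samples)
                if a.gxe_sd > 0
                else np.zeros(geno.n_samples)
            )
            rep_eff = (
                rng.normal(0.0, a.rep_sd, size=n_reps)
                if a.rep_sd > 0
                else np.zeros(n_reps)
            )
            genetic = g_qtn + u_poly + gxe
            env_h2[label] = true_h2
            for r in range(n_reps):
                eps = rng.normal(0.0, a.residual_sd, size=geno.n_samples)
                values = mu + genetic + rep_eff[r] + eps
                for i, s in enumerate(geno.samples):
                    records.append((s, a.trait, year, regime, r + 1, values[i]))
        truth[a.trait] = {
            "qtns": list(zip(a.qtn_positions, a.qtn_effects)),
            "h2": env_h2,
            "genetic_values": g_qtn + u_poly,
        }

    pheno = pd.DataFrame(
        records, columns=["variety", "trait", "year", "regime", "rep", "value"]
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# gene models and expression
# ---------------------------------------------------------------------------

def simulate_genes(
    chrom_lengths: dict[str, int],
    n_genes: int,
    seed: int = 0,
    length_range: tuple[int, int] = (1_000, 6_000),
) -> pd.DataFrame:
    """Scatter gene models (1-based inclusive coordinates) over chromosomes."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-lengths)[: n_genes - counts.sum()]:
        counts[i] += 1
    rows = []
    g = 0
    for chrom, length, k in zip(chroms, lengths, counts):
        starts = np.sort(rng.integers(1, int(length) - length_range[1], size=k))
        glens = rng.integers(length_range[0], length_range[1], size=k)
        strands = np.where(rng.random(k) < 0.5, "+", "-")
        for s, gl, st in zip(starts, glens, strands):
            g += 1
            rows.append((f"gene{g:05d}", chrom, int(s), int(s + gl - 1), st))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


@dataclass
class ExprSimConfig:
    """Expression-count simulation settings.

    Defaults emulate the validation RNA-seq design: contrasting high/low
    yield varieties, leaf and seed tissue, drought vs control, 3 biological
    replicates, negative-binomial counts.
    """

    n_genes: int = 2_000
    deg_fraction: float = 0.10
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    dispersion: float = 0.05
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    link_to_qtn_window_bp: int = 288_000
    varieties: tuple[str, ...] = ("G19", "G111")
    tissues: tuple[str, ...] = ("leaf", "seed")
    n_reps: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.deg_fraction < 1.0):
            raise ValueError("deg_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass
class ExpressionMatrix:
    """Gene × sample counts with gene lengths and a sample sheet.

    ``samples`` has columns sample, variety, tissue, treatment, replicate
    with treatment ∈ {control, drought}.
    """

    counts: pd.DataFrame  # genes × samples, integer
    lengths: pd.Series  # bp per gene
    samples: pd.DataFrame

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def simulate_expression(
    genes: pd.DataFrame, cfg: ExprSimConfig, qtns: list[tuple[str, int]] | None = None
):
    """Simulate NB counts with DEGs planted preferentially near QTNs.

    Gene-level mean counts scale with gene length and a log-normal baseline;
    drought samples of DEG genes are shifted by the planted log2 fold
    change.  Returns ``(expr, truth)`` where truth is a DataFrame of planted
    DEGs with their log2fc.
    """
    cfg.validate()
    if (genes["end"] - genes["start"]).min() < 0 or (
        genes["end"] - genes["start"] + 1
    ).min() <= 0:
        raise ValueError("gene lengths must be positive")
    rng = np.random.default_rng(cfg.seed)
    genes = genes.iloc[: cfg.n_genes].reset_index(drop=True)
    n = len(genes)
    gene_len = (genes["end"] - genes["start"] + 1).astype(int)

    n_deg = int(round(cfg.deg_fraction * n))
    near = np.zeros(n, dtype=bool)
    if qtns:
        for chrom, pos in qtns:
            on = genes["chrom"].to_numpy() == chrom
            dist = np.maximum(
                genes["start"].to_numpy() - pos, pos - genes["end"].to_numpy()
            )
            near |= on & (np.maximum(dist, 0) <= cfg.link_to_qtn_window_bp)
    near_idx = np.flatnonzero(near)
    far_idx = np.flatnonzero(~near)
    take_near = min(len(near_idx), n_deg)
    deg_idx = list(rng.choice(near_idx, size=take_near, replace=False))
    if n_deg - take_near > 0:
        deg_idx += list(rng.choice(far_idx, size=n_deg - take_near, replace=False))
    deg_idx = np.array(sorted(deg_idx), dtype=int)

    lfc = np.zeros(n)
    if n_deg:
        mag = rng.normal(cfg.lfc_mean, cfg.lfc_sd, size=len(deg_idx))
        sign = np.where(rng.random(len(deg_idx)) < 0.5, 1.0, -1.0)
        lfc[deg_idx] = mag * sign

    rows = []
    for v in cfg.varieties:
        for t in cfg.tissues:
            for trt in ("control", "drought"):
                for r in range(1, cfg.n_reps + 1):
                    rows.append((f"{v}_{t}_{trt}_{r}", v, t, trt, r))
    samples = pd.DataFrame(
        rows, columns=["sample", "variety", "tissue", "treatment", "replicate"]
    )

    base = rng.lognormal(mean=1.0, sigma=1.2, size=n) * (gene_len.to_numpy() / 1e3)
    rel = base / base.sum()
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    shape = 1.0 / cfg.dispersion
    for j, row in samples.iterrows():
        lib = rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1)
        mu = rel * lib
        if row["treatment"] == "drought":
            mu = mu * np.exp2(lfc)
        lam = rng.gamma(shape, mu / shape)
        counts[:, j] = rng.poisson(lam)

    expr = ExpressionMatrix(
        counts=pd.DataFrame(
            counts, index=genes["gene_id"].to_numpy(), columns=samples["sample"]
        ),
        lengths=pd.Series(gene_len.to_numpy(), index=genes["gene_id"].to_numpy()),
        samples=samples,
    )
    truth = pd.DataFrame(
        {"gene_id": genes["gene_id"].to_numpy()[deg_idx], "log2fc": lfc[deg_idx]}
    )
    return expr, truth
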