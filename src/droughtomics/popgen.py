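"""SNP QC, diversity, linkage disequilibrium and population-structure tools.

Implements the marker-side statistics of the pipeline: the QC filter chain
(call rate ≥ 0.90, biallelic, MAF ≥ 0.05, missingness ≤ 0.10), polymorphism
information content, pairwise r²/D′ (D′ via two-locus EM on unphased
diploids), Hill–Weir LD-decay fitting with a half-of-intercept decay
distance, the VanRaden centred genomic relationship matrix, PCA structure
covariates, and Gabriel confidence-interval haplotype blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic_data import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Per-stage removal counts; reasons sum to (input − output)."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())


def filter_snps(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.05,
    max_missing: float = 0.10,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sequential SNP QC: call rate → biallelic → MAF → missingness.

    Boundaries are inclusive on the keep side (call_rate ≥ 0.90, MAF ≥ 0.05,
    missing ≤ 0.10).  Removing every SNP is allowed and produces an empty
    matrix rather than an error.
    """
    if geno.n_snps == 0:
        raise ValueError("empty genotype matrix")
    report = QcReport(n_input=geno.n_snps)
    keep = np.ones(geno.n_snps, dtype=bool)

    cr = geno.call_rate()
    fail = keep & (cr < min_call_rate)
    report.removed["call_rate"] = int(fail.sum())
    keep &= ~fail

    if biallelic_only:
        ref = geno.snps["ref"].astype(str)
        alt = geno.snps["alt"].astype(str)
        bial = (ref.str.len() == 1) & (alt.str.len() == 1) & ~alt.str.contains(",")
        fail = keep & ~bial.to_numpy()
        report.removed["not_biallelic"] = int(fail.sum())
        keep &= ~fail

    maf = geno.maf()
    fail = keep & (maf < min_maf)
    report.removed["maf"] = int(fail.sum())
    keep &= ~fail

    miss = 1.0 - cr
    fail = keep & (miss > max_missing)
    report.removed["missingness"] = int(fail.sum())
    keep &= ~fail

    return geno.subset_snps(keep), report


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def pic(geno: GenotypeMatrix) -> np.ndarray:
    """Polymorphism information content per biallelic SNP.

    PIC = 1 − (p² + q²) − 2p²q², with p from non-missing calls; the maximum
    for a biallelic locus is 0.375 at p = 0.5, and a monomorphic locus gives 0.
    """
    d = geno.dosage_float()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

def _em_haplotype_freqs(
    ga: np.ndarray, gb: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray | None:
    """EM estimate of the 4 haplotype frequencies (AB, Ab, aB, ab) from
    unphased dosages at two loci; None when < 5 complete observations.

    'A'/'B' denote the alt allele at each locus.  Only the double
    heterozygote is phase-ambiguous.
    """
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    n = len(ga)
    if n < 5:
        return None
    counts = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        counts[i, j] += 1

    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    f = np.array(
        [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
    )  # AB, Ab, aB, ab
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n_dh = counts[1, 1]
    # contributions of unambiguous genotypes to haplotype counts
    base = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # AB
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],  # Ab
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # aB
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # ab
        ],
        dtype=float,
    )
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= new.sum()
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return f


def _dprime_from_freqs(f: np.ndarray) -> tuple[float, float]:
    """(D, D′) from haplotype frequencies (AB, Ab, aB, ab)."""
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    d = f[0] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return float(d), float(min(dprime, 1.0))


def pairwise_ld(
    geno: GenotypeMatrix,
    max_distance: int | None = None,
    within_chrom: bool = True,
    compute_dprime: bool = True,
    min_obs: int = 5,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs (optionally distance-capped) with
    r² from pairwise-complete dosage correlation and D′ from EM haplotype
    frequencies.

    Pairs with fewer than ``min_obs`` complete observations are skipped; the
    skip count is attached as ``df.attrs['n_skipped']``.
    """
    snps = geno.snps
    order = snps.sort_values(["chrom", "pos"]).index.to_numpy()
    d = geno.dosage_float()
    chroms = snps["chrom"].to_numpy()
    poss = snps["pos"].to_numpy()
    ids = snps["id"].to_numpy()

    frames = []
    skipped = 0
    no_missing = not np.isnan(d).any()
    for ci in pd.unique(chroms):
        idx = order[chroms[order] == ci]
        if len(idx) < 2:
            continue
        pos = poss[idx].astype(np.int64)
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = pos[jj] - pos[ii]
        if max_distance is not None:
            keep = dist <= max_distance
            ii, jj, dist = ii[keep], jj[keep], dist[keep]
        x = d[:, idx]
        if no_missing:
            sd = x.std(axis=0)
            valid = sd > 0
            xs = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
            corr = (xs.T @ xs) / x.shape[0]
            r2 = corr[ii, jj] ** 2
            nobs = np.full(len(ii), x.shape[0])
            ok = valid[ii] & valid[jj]
            skipped += int((~ok).sum())
            ii, jj, dist, r2, nobs = ii[ok], jj[ok], dist[ok], r2[ok], nobs[ok]
        else:
            r2 = np.empty(len(ii))
            nobs = np.empty(len(ii), dtype=int)
            ok = np.ones(len(ii), dtype=bool)
            for k, (a, b) in enumerate(zip(ii, jj)):
                xa, xb = x[:, a], x[:, b]
                use = ~np.isnan(xa) & ~np.isnan(xb)
                if use.sum() < min_obs or xa[use].std() == 0 or xb[use].std() == 0:
                    ok[k] = False
                    continue
                r = np.corrcoef(xa[use], xb[use])[0, 1]
                r2[k] = r * r
                nobs[k] = int(use.sum())
            skipped += int((~ok).sum())
            ii, jj, dist, r2, nobs = ii[ok], jj[ok], dist[ok], r2[ok], nobs[ok]
        dprime = np.full(len(ii), np.nan)
        if compute_dprime:
            for k, (a, b) in enumerate(zip(ii, jj)):
                f = _em_haplotype_freqs(geno.dosage[:, idx[a]], geno.dosage[:, idx[b]])
                if f is not None:
                    _, dprime[k] = _dprime_from_freqs(f)
        frames.append(
            pd.DataFrame(
                {
                    "snp_a": ids[idx[ii]],
                    "snp_b": ids[idx[jj]],
                    "chrom": ci,
                    "distance": dist,
                    "r2": r2,
                    "d_prime": dprime,
                    "n": nobs,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=["snp_a", "snp_b", "chrom", "distance", "r2", "d_prime", "n"]
        )
    out.attrs["n_skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def hill_weir_expected_r2(distance: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Drift-recombination expectation of r² as a function of C = ρ·distance
    for a sample of n chromosomes."""
    c = rho * np.asarray(distance, dtype=float)
    t1 = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    t2 = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c * c)) / (
        n * (2.0 + c) * (11.0 + c)
    )
    return t1 * t2


def _fit_hw_half_decay(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, n_chrom_copies: int
) -> dict:
    """Least-squares Hill–Weir fit and half-of-fitted-intercept distance.

    A free multiplicative scale absorbs the difference between the
    drift-expectation intercept and the data's short-range plateau, so the
    decay distance is governed by the fitted shape alone; flat curves fit
    ρ ≈ 0 and come back right-censored.
    """
    out: dict = {}
    (rho, scale), _ = optimize.curve_fit(
        lambda d, rho, a: a * hill_weir_expected_r2(d, rho, n_chrom_copies),
        x,
        y,
        p0=[1e-5, 1.0],
        sigma=1.0 / np.maximum(w, 1e-9),
        bounds=([1e-12, 1e-3], [1.0, 10.0]),
        maxfev=10_000,
    )
    d0 = float(x.min())
    curve = lambda d: scale * hill_weir_expected_r2(np.array([d]), rho, n_chrom_copies)[0]
    target = curve(d0) / 2.0
    dmax = float(x.max())
    f = lambda d: curve(d) - target
    if f(dmax) > 0:
        out.update(decay_distance=dmax, censored=True, rho=float(rho), scale=float(scale))
    else:
        out.update(
            decay_distance=float(optimize.brentq(f, d0, dmax)),
            censored=False,
            rho=float(rho),
            scale=float(scale),
        )
    return out


def expected_decay_distance(cfg, n_samples: int, dmax: int | None = None) -> float:
    """Deterministic decay distance implied by a simulator configuration.

    Evaluates the simulator's analytic expected-r² curve on a log-spaced
    distance grid, adds the finite-sample inflation of estimated r²
    (≈ (1 − r²)/n for n samples), and pushes the result through the same
    Hill–Weir fit and half-of-fitted-intercept rule as :func:`ld_decay`,
    so it is the deterministic target that the estimator recovers from
    simulated unstructured data.  Population structure adds long-range
    admixture LD on top of this expectation.
    """
    from .synthetic_data import expected_r2_curve

    if dmax is None:
        dmax = int(3 * cfg.ld_block_len)
    x = np.unique(np.logspace(1, np.log10(dmax), 40).astype(int)).astype(float)
    y = expected_r2_curve(cfg, x)
    y = y + (1.0 - y) / n_samples
    # pair density grows roughly linearly with distance bin width on a log grid
    w = np.sqrt(x)
    fit = _fit_hw_half_decay(x, y, w, 2 * n_samples)
    return float(fit["decay_distance"])


def ld_decay(
    ld_pairs: pd.DataFrame,
    n_samples: int,
    n_bins: int = 50,
    per_chrom: bool = False,
) -> dict:
    """Fit the Hill–Weir curve to binned r² and report the decay distance.

    The curve is fitted by least squares on mean r² in log-spaced distance
    bins; the decay distance is where the fitted curve falls to half its
    fitted value at the shortest observed distance.  If the fit fails, a
    binned half-max fallback is used and flagged.  A decay distance beyond
    the largest observed distance is reported as right-censored.
    """
    if len(ld_pairs) < 100:
        raise ValueError("need ≥ 100 LD pairs to fit a decay curve")
    sub = ld_pairs[ld_pairs["distance"] > 0]
    n_chrom_copies = 2 * n_samples

    edges = np.unique(
        np.logspace(
            np.log10(max(sub["distance"].min(), 1)),
            np.log10(sub["distance"].max() + 1),
            n_bins + 1,
        )
    )
    bins = pd.cut(sub["distance"], edges, include_lowest=True)
    grouped = sub.groupby(bins, observed=True)
    curve = pd.DataFrame(
        {
            "distance": grouped["distance"].mean(),
            "mean_r2": grouped["r2"].mean(),
            "n_pairs": grouped["r2"].size(),
        }
    ).dropna()

    x = curve["distance"].to_numpy()
    y = curve["mean_r2"].to_numpy()
    w = np.sqrt(curve["n_pairs"].to_numpy(dtype=float))
    result = {"curve": curve.reset_index(drop=True), "fallback": False}
    try:
        result.update(_fit_hw_half_decay(x, y, w, n_chrom_copies))
    except (RuntimeError, ValueError):
        # fallback: first bin whose mean r² drops below half of the first bin
        result["fallback"] = True
        half = y[0] / 2.0
        below = np.flatnonzero(y <= half)
        if len(below) == 0:
            result.update(decay_distance=float(x.max()), censored=True, rho=np.nan)
        else:
            result.update(
                decay_distance=float(x[below[0]]), censored=False, rho=np.nan
            )
    return result


# ---------------------------------------------------------------------------
# kinship and PCA
# ---------------------------------------------------------------------------

def kinship(geno: GenotypeMatrix, method: str = "vanraden") -> np.ndarray:
    """Genomic relationship matrix.

    ``vanraden``: G = ZZ′ / (2Σp(1−p)) with Z the allele-frequency-centred
    dosage matrix (missing dosages mean-imputed for this computation only).
    ``ibs``: proportion of shared alleles, scaled to the same diagonal
    convention.
    """
    d = geno.dosage_float()
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for kinship")
    d = d[:, poly]
    p = p[poly]
    d = np.where(np.isnan(d), 2.0 * p, d)
    if method == "vanraden":
        z = d - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        return (z @ z.T) / denom
    if method == "ibs":
        m = d.shape[1]
        sim = 1.0 - np.abs(d[:, None, :] - d[None, :, :]).sum(axis=2) / (2.0 * m)
        return 2.0 * sim - 1.0
    raise ValueError(f"unknown kinship method {method!r}")


def pca(geno: GenotypeMatrix, n_components: int = 5) -> dict:
    """PCA of centred dosages (missing mean-imputed).

    Returns scores (n × k), explained-variance ratios and SNP loadings with
    a deterministic sign convention (the largest-magnitude loading of each
    component is positive).
    """
    d = geno.dosage_float()
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu, d) - mu
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    rank = int((s > 1e-10).sum())
    k = min(n_components, rank)
    ev = s**2 / max(geno.n_samples - 1, 1)
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    return {
        "scores": u[:, :k] * s[:k],
        "explained_variance_ratio": ev[:k] / ev.sum(),
        "loadings": vt[:k].T,
        "truncated": k < n_components,
    }


# ---------------------------------------------------------------------------
# haplotype blocks (Gabriel CI method)
# ---------------------------------------------------------------------------

def _dprime_ci(
    ga: np.ndarray, gb: np.ndarray, grid: int = 101, mass: float = 0.90
) -> tuple[float, float] | None:
    """Likelihood-based confidence bounds on |D′| for one unphased pair.

    The likelihood of the 3×3 genotype table is profiled over |D′| on a grid
    (allele frequencies fixed at their marginal estimates, sign of D at its
    EM estimate), normalised to a distribution, and the central ``mass``
    interval returned — the unphased analogue of the Gabriel et al. bounds.
    """
    ok = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[ok].astype(int), gb[ok].astype(int)
    if len(ga) < 5:
        return None
    f_em = _em_haplotype_freqs(ga, gb)
    if f_em is None:
        return None
    d_em, _ = _dprime_from_freqs(f_em)
    sign = 1.0 if d_em >= 0 else -1.0
    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    if sign >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    counts = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        counts[i, j] += 1

    dprimes = np.linspace(0.0, 1.0, grid)
    loglik = np.full(grid, -np.inf)
    for t, dp in enumerate(dprimes):
        dval = sign * dp * dmax
        f = np.array(
            [
                pa * pb + dval,
                pa * (1 - pb) - dval,
                (1 - pa) * pb - dval,
                (1 - pa) * (1 - pb) + dval,
            ]
        )
        if (f < -1e-12).any():
            continue
        f = np.clip(f, 1e-12, None)
        # genotype probabilities under HWE on haplotype frequencies
        probs = np.zeros((3, 3))
        # dosage at locus a: number of alt haplotypes among {h1,h2}
        hap_a = np.array([1, 1, 0, 0])
        hap_b = np.array([1, 0, 1, 0])
        for h1 in range(4):
            for h2 in range(4):
                probs[hap_a[h1] + hap_a[h2], hap_b[h1] + hap_b[h2]] += f[h1] * f[h2]
        with np.errstate(divide="ignore"):
            loglik[t] = float((counts * np.log(np.clip(probs, 1e-300, None))).sum())
    like = np.exp(loglik - loglik.max())
    like /= like.sum()
    cdf = np.cumsum(like)
    alpha = (1.0 - mass) / 2.0
    lo = dprimes[np.searchsorted(cdf, alpha)]
    hi = dprimes[min(np.searchsorted(cdf, 1.0 - alpha), grid - 1)]
    return float(lo), float(hi)


def haplotype_blocks(
    geno: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    strong_upper: float = 0.98,
    strong_lower: float = 0.70,
    recomb_upper: float = 0.90,
    min_strong_fraction: float = 0.95,
) -> list[dict]:
    """Gabriel confidence-interval haplotype blocks.

    A pair is in *strong LD* when its D′ CI has upper ≥ 0.98 and lower
    ≥ 0.70, and shows *strong recombination* when the upper bound < 0.90;
    other pairs are uninformative.  A candidate span is a block when its
    outermost pair is strong and ≥ 95% of its informative pairs are strong.
    Blocks are taken greedily longest-first without overlap.
    """
    snps = geno.snps
    if region is not None:
        chrom, lo, hi = region
        mask = (
            (snps["chrom"] == chrom) & (snps["pos"] >= lo) & (snps["pos"] <= hi)
        ).to_numpy()
        idx = np.flatnonzero(mask)
    else:
        idx = np.arange(len(snps))
    idx = idx[np.argsort(snps["pos"].to_numpy()[idx], kind="stable")]
    if len(idx) < 2:
        return []

    m = len(idx)
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            ci = _dprime_ci(geno.dosage[:, idx[i]], geno.dosage[:, idx[j]])
            if ci is None:
                continue
            lo_b, hi_b = ci
            if hi_b >= strong_upper and lo_b >= strong_lower:
                strong[i, j] = informative[i, j] = True
            elif hi_b < recomb_upper:
                informative[i, j] = True

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if not strong[i, j]:
                continue
            n_inf = informative[i : j + 1, i : j + 1].sum()
            n_str = strong[i : j + 1, i : j + 1].sum()
            if n_inf == 0 or n_str / n_inf < min_strong_fraction:
                continue
            span = int(snps["pos"].iloc[idx[j]] - snps["pos"].iloc[idx[i]])
            candidates.append((span, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))

    used = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        members = idx[i : j + 1]
        blocks.append(
            {
                "chrom": snps["chrom"].iloc[members[0]],
                "start": int(snps["pos"].iloc[members[0]]),
                "end": int(snps["pos"].iloc[members[-1]]),
                "snps": [snps["id"].iloc[k] for k in members],
            }
        )
    blocks.sort(key=lambda b: (b["chrom"], b["start"]))
    return blocks
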