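"""Single-marker genome-wide association under GLM and MLM.

The GLM regresses per-variety trait means on additive dosage plus an
intercept and structure covariates (PCA scores by default, a user Q matrix
optionally).  The MLM adds a polygenic random effect u ~ N(0, K·σu²) with K
the genomic relationship matrix; variance components are estimated once on
the null model by REML through the spectral decomposition of K and then
fixed for every marker (the P3D/EMMAX approximation), after which each SNP
is tested by a Wald test under generalized least squares.

Downstream utilities implement the study's reporting conventions: the fixed
P < 10⁻⁴ significance threshold (strict inequality), per-SNP R² from nested
models, stability across year × regime environments, pleiotropy across
traits, Tukey-HSD allele-class comparisons, and genomic-inflation / QQ /
Manhattan tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import MISSING, CHROMOSOMES, GenotypeMatrix

ALPHA_DEFAULT = 1e-4


def _variety_means(pheno: pd.DataFrame, trait: str, environment) -> pd.Series:
    from .quantgen import _cell

    sub = _cell(pheno, trait, environment)
    return sub.groupby("variety")["value"].mean()


def _align_phenotype(geno: GenotypeMatrix, y: pd.Series) -> np.ndarray:
    yv = y.reindex(geno.samples)
    if yv.isna().all():
        raise ValueError("phenotype does not overlap genotype samples")
    return yv.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def glm_assoc(
    geno: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    covariates: np.ndarray | None = None,
    trait: str = "",
    environment: str = "",
    model_tag: str = "GLM+PC",
) -> pd.DataFrame:
    """Per-SNP ordinary least squares of phenotype on dosage + covariates.

    ``y`` is the per-variety mean for one trait × environment, indexed by
    sample name (or an array aligned to ``geno.samples``).  Samples with a
    missing call are dropped per SNP; monomorphic SNPs (after drops) are
    flagged untestable with p = NaN.
    """
    yv = _align_phenotype(geno, y) if isinstance(y, pd.Series) else np.asarray(y, float)
    n = geno.n_samples
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])

    d = geno.dosage
    results = []
    ok_y = ~np.isnan(yv)
    for j in range(geno.n_snps):
        s = d[:, j].astype(float)
        ok = ok_y & (d[:, j] != MISSING)
        nj = int(ok.sum())
        if nj <= X0.shape[1] + 1 or np.ptp(s[ok]) == 0:
            results.append((np.nan, np.nan, np.nan, nj, False))
            continue
        X = np.column_stack([X0[ok], s[ok]])
        beta, sse, rank, _ = _ols(X, yv[ok])
        dfree = nj - X.shape[1]
        if dfree <= 0 or sse <= 0:
            # perfect fit: effect recovered, p underflows to ~0
            results.append((beta[-1], 0.0, 1.0, nj, True))
            continue
        sigma2 = sse / dfree
        xtx_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[-1, -1])
        tstat = beta[-1] / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tstat), dfree)
        # nested-model R² on the same samples
        _, sse0, _, _ = _ols(X0[ok], yv[ok])
        sst = float(((yv[ok] - yv[ok].mean()) ** 2).sum())
        r2 = (sse0 - sse) / sst if sst > 0 else np.nan
        results.append((beta[-1], max(p, np.finfo(float).tiny), r2, nj, True))

    out = geno.snps[["id", "chrom", "pos"]].copy()
    out["trait"] = trait
    out["environment"] = environment
    out["model"] = model_tag
    out[["effect", "p", "r2", "n"]] = pd.DataFrame(
        [r[:4] for r in results], index=out.index
    )
    out["testable"] = [r[4] for r in results]
    return out


def _ols(X: np.ndarray, y: np.ndarray):
    beta, res, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    return beta, sse, rank, sv


def snp_r2(
    X_reduced: np.ndarray, X_full: np.ndarray, y: np.ndarray
) -> float:
    """Nested-model variance explained: (SSE_reduced − SSE_full)/SST."""
    _, sse_r, _, _ = _ols(X_reduced, y)
    _, sse_f, _, _ = _ols(X_full, y)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    return (sse_r - sse_f) / sst


# ---------------------------------------------------------------------------
# MLM (P3D / EMMAX)
# ---------------------------------------------------------------------------

def _reml_delta(
    eigenvalues: np.ndarray, Uy: np.ndarray, UX: np.ndarray
) -> float:
    """REML estimate of δ = σe²/σu² on the rotated null model.

    Profile REML log-likelihood in δ is maximised on a log grid refined by
    bounded scalar optimisation (the EMMA formulation).
    """
    n, p = UX.shape

    def neg_reml_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        v = eigenvalues + delta
        w = 1.0 / v
        XtWX = (UX * w[:, None]).T @ UX
        XtWy = (UX * w[:, None]).T @ Uy
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = Uy - UX @ beta
        rss = float((r * r * w).sum())
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * (np.log(2.0 * np.pi * rss / (n - p)) + 1.0)
            + np.log(v).sum()
            + logdet_XtWX
        )
        return -ll

    grid = np.linspace(-10.0, 10.0, 41)
    vals = [neg_reml_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml_ll, bounds=(lo, hi), method="bounded")
    return float(np.exp(res.x))


def mlm_assoc(
    geno: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    trait: str = "",
    environment: str = "",
    model_tag: str = "MLM+K+PC",
) -> pd.DataFrame:
    """Mixed-model association with kinship random effect (P3D/EMMAX).

    y = Xβ + s·a + u + e with u ~ N(0, K·σu²), e ~ N(0, I·σe²).  The
    variance ratio δ = σe²/σu² is REML-estimated once on the null model via
    the spectral decomposition of K and then fixed for every SNP; each
    marker is tested by a Wald t-test on its GLS coefficient.  Missing
    dosages are mean-imputed so the single rotation stays valid.
    """
    yv = _align_phenotype(geno, y) if isinstance(y, pd.Series) else np.asarray(y, float)
    n = geno.n_samples
    K = np.asarray(K, dtype=float)
    eigvals, U = np.linalg.eigh((K + K.T) / 2.0)
    if eigvals.min() < -1e-8:
        K = K + (1e-6 - eigvals.min()) * np.eye(n)
        eigvals, U = np.linalg.eigh(K)
    eigvals = np.clip(eigvals, 0.0, None)

    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, np.asarray(covariates, dtype=float)])
    Uy = U.T @ yv
    UX0 = U.T @ X0
    delta = _reml_delta(eigvals, Uy, UX0)
    w = 1.0 / (eigvals + delta)
    sw = np.sqrt(w)

    # pre-whitened null design and phenotype
    yt = Uy * sw
    X0t = UX0 * sw[:, None]

    d = geno.dosage_float()
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu, d)
    Ud = (U.T @ d) * sw[:, None]

    # project out the null design from yt and each SNP column
    Q0, _ = np.linalg.qr(X0t)
    y_res = yt - Q0 @ (Q0.T @ yt)
    S_res = Ud - Q0 @ (Q0.T @ Ud)

    sxx = (S_res**2).sum(axis=0)
    sxy = S_res.T @ y_res
    dfree = n - X0t.shape[1] - 1
    testable = sxx > 1e-12
    effect = np.full(geno.n_snps, np.nan)
    pvals = np.full(geno.n_snps, np.nan)
    r2 = np.full(geno.n_snps, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(testable, sxy / sxx, np.nan)
        syy = float(y_res @ y_res)
        sse = syy - np.where(testable, sxy**2 / sxx, 0.0)
        sse = np.clip(sse, 0.0, None)
        se = np.sqrt(sse / dfree / sxx)
        tstat = a / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), dfree)
    effect[testable] = a[testable]
    pvals[testable] = np.clip(pv[testable], np.finfo(float).tiny, 1.0)
    # likelihood-ratio-based analogue of marker R² on the whitened scale
    with np.errstate(invalid="ignore", divide="ignore"):
        lr = -dfree * np.log(np.clip(sse / syy, 1e-300, None))
    r2[testable] = 1.0 - np.exp(-lr[testable] / max(n, 1))

    out = geno.snps[["id", "chrom", "pos"]].copy()
    out["trait"] = trait
    out["environment"] = environment
    out["model"] = model_tag
    out["effect"] = effect
    out["p"] = pvals
    out["r2"] = r2
    out["n"] = n
    out["testable"] = testable
    out.attrs["delta"] = delta
    out.attrs["h2_pseudo"] = 1.0 / (1.0 + delta)
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def significant_snps(results: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """SNPs with p strictly below alpha, deduplicated by (snp, trait, env)."""
    if results.empty:
        return results.copy()
    sig = results[results["p"] < alpha].copy()
    return sig.drop_duplicates(subset=["id", "trait", "environment"]).reset_index(
        drop=True
    )


def stable_snps(sig: pd.DataFrame, min_environments: int = 2) -> pd.DataFrame:
    """SNPs significant for the same trait in ≥ 2 year×regime environments.

    Output is a wide table (one row per SNP × trait, one column per
    environment holding the p-value, "ns" where not significant).
    """
    if sig.empty:
        return pd.DataFrame()
    counts = sig.groupby(["id", "trait"])["environment"].nunique()
    keep = counts[counts >= min_environments].index
    sub = sig.set_index(["id", "trait"]).loc[keep].reset_index()
    wide = sub.pivot_table(
        index=["trait", "id", "chrom", "pos"],
        columns="environment",
        values="p",
        aggfunc="min",
    )
    wide = wide.map(lambda v: v if pd.notna(v) else "ns").reset_index()
    wide.columns.name = None
    return wide


def pleiotropic_snps(sig: pd.DataFrame, min_traits: int = 2) -> pd.DataFrame:
    """SNPs significant for ≥ 2 traits (any environment), one row per SNP."""
    if sig.empty:
        return pd.DataFrame()
    counts = sig.groupby("id")["trait"].nunique()
    keep = counts[counts >= min_traits].index
    sub = sig[sig["id"].isin(keep)]
    if sub.empty:
        return pd.DataFrame(
            columns=["id", "chrom", "pos", "n_traits", "traits", "min_p"]
        )
    rows = []
    for snp, grp in sub.groupby("id"):
        rows.append(
            {
                "id": snp,
                "chrom": grp["chrom"].iloc[0],
                "pos": grp["pos"].iloc[0],
                "n_traits": grp["trait"].nunique(),
                "traits": ",".join(sorted(grp["trait"].unique())),
                "min_p": grp["p"].min(),
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


def allele_effects(
    geno: GenotypeMatrix,
    y: pd.Series,
    snp_id: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotype-class means with Tukey HSD letter groupings for one SNP.

    Classes are the ref/het/alt genotype strings (e.g. AA/AG/GG); classes
    with fewer than 2 members are reported but excluded from testing.
    Classes sharing a letter are not significantly different at family
    level ``alpha``.
    """
    import networkx as nx
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    j = geno.snps.index[geno.snps["id"] == snp_id]
    if len(j) == 0:
        raise KeyError(f"SNP {snp_id} not found")
    j = int(j[0])
    ref, alt = geno.snps["ref"].iloc[j], geno.snps["alt"].iloc[j]
    labels = {0: ref + ref, 1: "".join(sorted(ref + alt)), 2: alt + alt}
    dos = geno.dosage[:, j]
    yv = _align_phenotype(geno, y)
    ok = (dos != MISSING) & ~np.isnan(yv)
    classes = pd.Series([labels[int(g)] for g in dos[ok]], name="class")
    values = pd.Series(yv[ok], name="value")

    summary = (
        pd.DataFrame({"class": classes, "value": values})
        .groupby("class")["value"]
        .agg(["count", "mean", "std"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    tested = summary.loc[summary["n"] >= 2, "class"].tolist()
    letters = {c: "" for c in summary["class"]}
    if len(tested) >= 2:
        mask = classes.isin(tested).to_numpy()
        hsd = pairwise_tukeyhsd(values[mask], classes[mask], alpha=alpha)
        # letter display: maximal cliques of the "not significantly different" graph
        import itertools

        g = nx.Graph()
        g.add_nodes_from(tested)
        pairs = list(itertools.combinations(hsd.groupsunique, 2))
        for (a, b), reject in zip(pairs, np.asarray(hsd.reject)):
            if not reject:
                g.add_edge(a, b)
        order = summary.set_index("class")["mean"].sort_values(ascending=False)
        cliques = sorted(
            nx.find_cliques(g), key=lambda c: -max(order.get(x, -np.inf) for x in c)
        )
        for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
            for c in clique:
                letters[c] += letter
        letters = {c: "".join(sorted(v)) for c, v in letters.items()}
    summary["group"] = summary["class"].map(letters)
    summary["tested"] = summary["class"].isin(tested)
    return summary


def genomic_inflation(pvalues: np.ndarray) -> float:
    """λ = median observed χ²(1) / 0.4549 from two-sided p-values."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def inflation_and_plots(results: pd.DataFrame) -> dict:
    """Genomic inflation λ plus QQ and Manhattan plot tables.

    The Manhattan table carries a cumulative genome coordinate following
    chromosome order A01..A10, C01..C09.
    """
    res = results.dropna(subset=["p"])
    if len(res) < 100:
        raise ValueError("need ≥ 100 tests for calibration diagnostics")
    lam = genomic_inflation(res["p"].to_numpy())
    obs = -np.log10(np.sort(res["p"].to_numpy()))
    m = len(obs)
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": exp, "observed": obs})

    order = {c: i for i, c in enumerate(CHROMOSOMES)}
    man = res.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    offsets = {}
    cum = 0
    for chrom in sorted(man["chrom"].unique(), key=lambda c: order.get(c, 99)):
        offsets[chrom] = cum
        cum += int(man.loc[man["chrom"] == chrom, "pos"].max()) + 1
    man = man.assign(
        genome_pos=man["pos"] + man["chrom"].map(offsets),
        neg_log10_p=-np.log10(man["p"]),
    )
    return {"lambda": lam, "qq": qq, "manhattan": man.reset_index(drop=True)}


def lead_snps(sig: pd.DataFrame) -> pd.DataFrame:
    """One lead SNP per trait × environment peak: smallest p, then smallest pos."""
    if sig.empty:
        return sig.copy()
    ordered = sig.sort_values(["trait", "environment", "p", "pos"])
    return ordered.groupby(["trait", "environment"], as_index=False).first()
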