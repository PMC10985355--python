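"""ANOVA-based quantitative-genetic parameter estimation.

Per trait × environment, a randomized-complete-block ANOVA (genotype +
replicate) yields the genotype and error mean squares from which the
classical chain of genetic parameters is computed:

    σg² = (MSG − MSE) / r          genotypic variance
    σe² = MSE                      environmental (error) variance
    σp² = σg² + σe²                phenotypic variance
    ECV = 100·√MSE / x̄             environmental CV
    GCV = 100·σg / x̄               genotypic CV
    PCV = 100·σp / x̄               phenotypic CV
    h²  = 100·σg² / σp²            broad-sense heritability
    GA  = k · (h²/100) · σp        genetic advance (k = 1.76, top 10%)
    GAM = 100·GA / x̄               genetic advance over the mean

Negative σg² estimates are clamped to zero and flagged.  The combined
multi-environment analysis treats year as random and watering regime and
genotype as fixed, testing each fixed term against its interaction with
year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: standardized selection intensity for truncation of the top 10%
SELECTION_INTENSITY = 1.76


def selection_intensity(proportion: float = 0.10) -> float:
    """Mean of the selected upper tail of a standard normal.

    i = φ(z) / p with z the (1 − p) quantile; p = 0.10 gives ≈ 1.755.
    """
    if not (0 < proportion < 1):
        raise ValueError("proportion must be in (0, 1)")
    z = stats.norm.isf(proportion)
    return float(stats.norm.pdf(z) / proportion)


@dataclass
class AnovaTable:
    """ANOVA summary: one row per source with df, MS, F, p.

    ``r`` is the (harmonic-mean) replicate count used downstream for
    variance components.
    """

    rows: pd.DataFrame  # columns: source, df, ss, mean_square, f_value, p_value
    r: float

    def ms(self, source: str) -> float:
        row = self.rows.loc[self.rows["source"] == source]
        if row.empty:
            raise KeyError(f"no source {source!r} in ANOVA table")
        return float(row["mean_square"].iloc[0])


def _cell(pheno: pd.DataFrame, trait: str, environment: str | tuple) -> pd.DataFrame:
    sub = pheno[pheno["trait"] == trait]
    if isinstance(environment, tuple):
        year, regime = environment
        sub = sub[(sub["year"] == year) & (sub["regime"] == regime)]
    else:
        labels = sub["regime"] + (sub["year"] % 100).astype(int).astype(str).str.zfill(2)
        sub = sub[labels == environment]
    if sub.empty:
        raise ValueError(f"no observations for trait={trait}, environment={environment}")
    return sub


def anova_per_environment(
    pheno: pd.DataFrame, trait: str, environment: str | tuple
) -> AnovaTable:
    """Two-way genotype + replicate ANOVA for one trait × environment cell.

    Balanced layouts use closed-form sums of squares; unbalanced ones fall
    back to a sequential least-squares fit (type-I, genotype first after
    replicate).
    """
    sub = _cell(pheno, trait, environment)
    n_geno = sub["variety"].nunique()
    rep_counts = sub.groupby("variety")["rep"].count()
    if n_geno < 2:
        raise ValueError("need at least 2 genotypes")
    if rep_counts.min() < 2:
        raise ValueError("need at least 2 replicates per genotype")
    r_harm = len(rep_counts) / (1.0 / rep_counts).sum()

    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())

    balanced = sub.groupby(["variety", "rep"]).size().eq(1).all() and (
        rep_counts.nunique() == 1
    )
    if balanced:
        r = int(rep_counts.iloc[0])
        g_means = sub.groupby("variety")["value"].mean()
        r_means = sub.groupby("rep")["value"].mean()
        ss_g = float(r * ((g_means - grand) ** 2).sum())
        ss_r = float(n_geno * ((r_means - grand) ** 2).sum())
        ss_e = max(sst - ss_g - ss_r, 0.0)
        df_g, df_r = n_geno - 1, r - 1
        df_e = max(n - n_geno - r + 1, 1)
    else:
        # sequential fit: grand mean -> +replicate -> +genotype
        def rss(factors: list[str]) -> float:
            if not factors:
                return sst
            X = pd.get_dummies(sub[factors].astype(str), drop_first=False)
            Xm = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
            beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
            return float(((y - Xm @ beta) ** 2).sum())

        rss_r = rss(["rep"])
        rss_gr = rss(["rep", "variety"])
        ss_r = sst - rss_r
        ss_g = rss_r - rss_gr
        ss_e = rss_gr
        df_g = n_geno - 1
        df_r = sub["rep"].nunique() - 1
        df_e = max(n - 1 - df_g - df_r, 1)

    ms_g, ms_r, ms_e = ss_g / df_g, ss_r / max(df_r, 1), ss_e / df_e
    rows = []
    for source, df, ss, ms in (
        ("genotype", df_g, ss_g, ms_g),
        ("replicate", df_r, ss_r, ms_r),
        ("error", df_e, ss_e, ms_e),
    ):
        if source == "error":
            f, p = np.nan, np.nan
        elif ms_e > 0:
            f = ms / ms_e
            p = float(stats.f.sf(f, df, df_e))
        else:
            f = np.inf if ms > 0 else 0.0
            p = 0.0 if ms > 0 else 1.0
        rows.append((source, df, ss, ms, f, p))
    table = pd.DataFrame(
        rows, columns=["source", "df", "ss", "mean_square", "f_value", "p_value"]
    )
    return AnovaTable(rows=table, r=float(r_harm))


def combined_anova(pheno: pd.DataFrame, trait: str) -> AnovaTable:
    """Combined multi-environment ANOVA with year random, regime/genotype fixed.

    Sources: genotype (G), year (Y), regime (E), G×Y, G×E, Y×E, G×Y×E and
    residual error.  Fixed terms are tested against their interaction with
    the random year factor (G vs G×Y, E vs Y×E, G×E vs G×Y×E); year-involving
    terms are tested against the residual.

    With a single year the per-environment analysis is the right tool; this
    function then raises a ValueError directing there.
    """
    sub = pheno[pheno["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no observations for trait {trait}")
    if sub["year"].nunique() < 2 or sub["regime"].nunique() < 2:
        raise ValueError(
            "combined ANOVA needs ≥ 2 years and both regimes; "
            "use anova_per_environment for a single cell"
        )

    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())

    def ss_main(col) -> tuple[float, int]:
        g = sub.groupby(col)["value"].agg(["mean", "count"])
        return float((g["count"] * (g["mean"] - grand) ** 2).sum()), len(g) - 1

    ss_g, df_g = ss_main("variety")
    ss_y, df_y = ss_main("year")
    ss_e, df_e = ss_main("regime")

    def ss_inter(cols, lower) -> tuple[float, int]:
        g = sub.groupby(cols)["value"].agg(["mean", "count"])
        total = float((g["count"] * (g["mean"] - grand) ** 2).sum())
        df = int(np.prod([sub[c].nunique() - 1 for c in cols]))
        return total - lower, df

    ss_gy, df_gy = ss_inter(["variety", "year"], ss_g + ss_y)
    ss_ge, df_ge = ss_inter(["variety", "regime"], ss_g + ss_e)
    ss_ye, df_ye = ss_inter(["year", "regime"], ss_y + ss_e)
    ss_cells, _ = ss_inter(["variety", "year", "regime"], 0.0)
    ss_gye = ss_cells - ss_g - ss_y - ss_e - ss_gy - ss_ge - ss_ye
    ss_gye = max(ss_gye, 0.0)
    df_gye = df_g * df_y * df_e
    ss_err = max(sst - ss_cells, 0.0)
    df_err = max(n - (df_g + 1) * (df_y + 1) * (df_e + 1), 1)

    ms = {
        "genotype": ss_g / df_g,
        "year": ss_y / df_y,
        "regime": ss_e / df_e,
        "genotype:year": ss_gy / df_gy,
        "genotype:regime": ss_ge / df_ge,
        "year:regime": ss_ye / df_ye,
        "genotype:year:regime": ss_gye / df_gye,
        "error": ss_err / df_err,
    }
    dfs = {
        "genotype": df_g,
        "year": df_y,
        "regime": df_e,
        "genotype:year": df_gy,
        "genotype:regime": df_ge,
        "year:regime": df_ye,
        "genotype:year:regime": df_gye,
        "error": df_err,
    }
    sss = {
        "genotype": ss_g,
        "year": ss_y,
        "regime": ss_e,
        "genotype:year": ss_gy,
        "genotype:regime": ss_ge,
        "year:regime": ss_ye,
        "genotype:year:regime": ss_gye,
        "error": ss_err,
    }
    denom = {
        "genotype": "genotype:year",
        "regime": "year:regime",
        "genotype:regime": "genotype:year:regime",
        "year": "error",
        "genotype:year": "error",
        "year:regime": "error",
        "genotype:year:regime": "error",
    }
    rows = []
    for source in [
        "genotype",
        "year",
        "regime",
        "genotype:year",
        "genotype:regime",
        "year:regime",
        "genotype:year:regime",
        "error",
    ]:
        if source == "error":
            rows.append((source, dfs[source], sss[source], ms[source], np.nan, np.nan))
            continue
        dname = denom[source]
        if ms[dname] > 0:
            f = ms[source] / ms[dname]
            p = float(stats.f.sf(f, dfs[source], dfs[dname]))
        else:
            f = np.inf if ms[source] > 0 else 0.0
            p = 0.0 if ms[source] > 0 else 1.0
        rows.append((source, dfs[source], sss[source], ms[source], f, p))
    table = pd.DataFrame(
        rows, columns=["source", "df", "ss", "mean_square", "f_value", "p_value"]
    )
    rep_counts = sub.groupby(["variety", "year", "regime"]).size()
    r_harm = len(rep_counts) / (1.0 / rep_counts).sum()
    return AnovaTable(rows=table, r=float(r_harm))


def variance_components(anova: AnovaTable) -> dict:
    """σg² = (MSG − MSE)/r, σe² = MSE, σp² = σg² + σe².

    A negative σg² estimate (MSE > MSG) is clamped to 0 and flagged.
    """
    if anova.r <= 0:
        raise ValueError("replicate count r must be > 0")
    msg, mse = anova.ms("genotype"), anova.ms("error")
    sigma_g2 = (msg - mse) / anova.r
    clamped = sigma_g2 < 0
    sigma_g2 = max(sigma_g2, 0.0)
    return {
        "sigma_g2": sigma_g2,
        "sigma_e2": mse,
        "sigma_p2": sigma_g2 + mse,
        "negative_clamped": bool(clamped),
    }


def coefficients_of_variation(vc: dict, mean: float, mse: float) -> dict:
    """ECV, GCV, PCV as percentages of the trait mean (GCV ≤ PCV always)."""
    if mean <= 0:
        raise ValueError("trait mean must be > 0 for coefficients of variation")
    return {
        "ecv": 100.0 * np.sqrt(mse) / mean,
        "gcv": 100.0 * np.sqrt(vc["sigma_g2"]) / mean,
        "pcv": 100.0 * np.sqrt(vc["sigma_p2"]) / mean,
    }


def cv_class(cv: float) -> str:
    """Classify a CV: > 20 high, 10–20 moderate, < 10 low."""
    if cv > 20:
        return "high"
    if cv >= 10:
        return "moderate"
    return "low"


def heritability(sigma_g2: float, sigma_p2: float) -> float:
    """Broad-sense heritability in percent; NaN when σp² = 0."""
    if sigma_p2 < 0:
        raise ValueError("sigma_p2 must be ≥ 0")
    if sigma_p2 == 0:
        return float("nan")
    return 100.0 * sigma_g2 / sigma_p2


def genetic_advance(
    h2_percent: float, sigma_p: float, mean: float, k: float = SELECTION_INTENSITY
) -> tuple[float, float]:
    """Genetic advance GA = k·h²·σp and GAM = 100·GA/x̄ (h² as a fraction)."""
    if mean <= 0:
        raise ValueError("trait mean must be > 0")
    ga = k * (h2_percent / 100.0) * sigma_p
    return ga, 100.0 * ga / mean


def genetic_params_table(pheno: pd.DataFrame, k: float = SELECTION_INTENSITY) -> pd.DataFrame:
    """One row of genetic parameters per trait × environment.

    Summary statistics (mean, SD, min, max) are computed over variety means;
    variance components come from the per-environment ANOVA.
    """
    from .synthetic_data import env_label

    rows = []
    for (trait, year, regime), sub in pheno.groupby(["trait", "year", "regime"]):
        label = env_label(int(year), regime)
        an = anova_per_environment(pheno, trait, (int(year), regime))
        vc = variance_components(an)
        vmeans = sub.groupby("variety")["value"].mean()
        mean = float(vmeans.mean())
        cvs = coefficients_of_variation(vc, mean, vc["sigma_e2"])
        h2 = heritability(vc["sigma_g2"], vc["sigma_p2"])
        ga, gam = genetic_advance(h2, np.sqrt(vc["sigma_p2"]), mean, k=k)
        rows.append(
            {
                "trait": trait,
                "environment": label,
                "year": int(year),
                "regime": regime,
                "mean": mean,
                "sd": float(vmeans.std(ddof=1)),
                "min": float(vmeans.min()),
                "max": float(vmeans.max()),
                "sigma_g2": vc["sigma_g2"],
                "sigma_e2": vc["sigma_e2"],
                "sigma_p2": vc["sigma_p2"],
                "ecv": cvs["ecv"],
                "pcv": cvs["pcv"],
                "gcv": cvs["gcv"],
                "h2": h2,
                "ga": ga,
                "gam": gam,
                "k": k,
                "negative_clamped": vc["negative_clamped"],
            }
        )
    return pd.DataFrame(rows).sort_values(["trait", "year", "regime"]).reset_index(
        drop=True
    )


def percent_reduction(table: pd.DataFrame, trait: str) -> float:
    """Drought reduction: 100·(1 − mean of DS yearly means / mean of WW means)."""
    sub = table[table["trait"] == trait]
    ww = sub.loc[sub["regime"] == "WW", "mean"]
    ds = sub.loc[sub["regime"] == "DS", "mean"]
    if ww.empty or ds.empty:
        raise ValueError(f"trait {trait} missing one of the WW/DS regimes")
    return 100.0 * (1.0 - ds.mean() / ww.mean())


def trait_correlations(pheno: pd.DataFrame, regime: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between traits on variety means within a regime.

    Returns (r matrix, p matrix); a constant trait yields NaN with no error.
    """
    sub = pheno[pheno["regime"] == regime]
    wide = sub.groupby(["variety", "trait"])["value"].mean().unstack()
    if len(wide) < 3:
        raise ValueError("need at least 3 varieties for correlations")
    traits = list(wide.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            b = traits[j]
            x, yv = wide[a], wide[b]
            ok = x.notna() & yv.notna()
            if x[ok].std() == 0 or yv[ok].std() == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x[ok], yv[ok])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def contrast_groups(
    pheno: pd.DataFrame, high_ids: list[str], low_ids: list[str], trait: str
) -> dict:
    """Welch two-sample comparison of variety-mean trait values between groups."""
    if not high_ids or not low_ids:
        raise ValueError("both groups must be non-empty")
    if len(high_ids) < 2 or len(low_ids) < 2:
        raise ValueError("each group needs at least 2 varieties")
    sub = pheno[pheno["trait"] == trait]
    vmeans = sub.groupby("variety")["value"].mean()
    hi = vmeans.reindex(high_ids).dropna()
    lo = vmeans.reindex(low_ids).dropna()
    t, p = stats.ttest_ind(hi, lo, equal_var=False)
    return {
        "mean_high": float(hi.mean()),
        "mean_low": float(lo.mean()),
        "t": float(t),
        "p": float(p),
        "n_high": len(hi),
        "n_low": len(lo),
    }
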