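"""Somatic cis-eQTL screen and its downstream contingency statistics.

For every eligible gene-mutation combination (locus mutated in at least two
samples and linked to an expressed gene, either a non-synonymous coding
mutation or an enhancer mutation), expression z-scores are regressed on

    Exp ~ Mut + CNA + Purity + Tumour

where matched normal samples enter with Mut = 0, CNA = 2, Purity = 0,
Tumour = 0.  A combination is "explained" when the FDR-adjusted p of the
model F-statistic is below 0.01; individual variables are called at
coefficient FDR < 0.05.  Storey's pi0 estimates the overall fraction of
true nulls.  Companion routines implement the clonality classification,
sign/proportion contrasts, Fisher enrichment, external-cohort LRT
validation and the post hoc power rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_expressed",
    "zscore",
    "eligible_combinations",
    "EQTLModel",
    "fit_eqtl",
    "screen",
    "EQTLScreen",
    "storey_pi0",
    "classify_clonality",
    "direction_test",
    "clonality_proportion_test",
    "enrichment_fisher",
    "validate_external",
    "required_n",
]


def filter_expressed(tpm: pd.DataFrame, tumour_samples=None,
                     min_tpm: float = 10.0,
                     min_frac: float = 0.05) -> list[str]:
    """Genes with at least ``min_tpm`` TPM in at least ``min_frac`` of
    tumour samples."""
    mat = tpm if tumour_samples is None else tpm[list(tumour_samples)]
    frac = (mat >= min_tpm).mean(axis=1)
    return list(mat.index[frac >= min_frac])


def zscore(expression: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise z-scores over all samples; zero-variance genes flagged.

    Returns the z matrix (flagged genes as NaN rows) and the flagged list.
    """
    mean = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=0)
    flagged = list(expression.index[sd == 0])
    z = expression.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z, flagged


def eligible_combinations(mut: pd.DataFrame, links: pd.DataFrame,
                          min_samples: int = 2) -> pd.DataFrame:
    """Gene-mutation combinations entering the screen.

    ``links`` columns: locus, gene, class (non_synonymous / enhancer); a
    locus annotated under both classes (enhancer overlapping coding) yields
    one combination per class.  Loci mutated in fewer than ``min_samples``
    samples are excluded.
    """
    counts = mut.sum(axis=1)
    ok = set(counts.index[counts >= min_samples])
    out = links[links["locus"].isin(ok)].drop_duplicates(
        subset=["locus", "gene", "class"]).reset_index(drop=True)
    return out


@dataclass
class EQTLFit:
    """OLS fit of one gene-mutation combination."""

    params: pd.Series
    pvalues: pd.Series
    f_pvalue: float
    conf_int: pd.DataFrame
    nobs: int
    rsquared: float
    status: str = "ok"

    def summary(self) -> str:
        lines = ["Exp ~ Mut + CNA + Purity + Tumour  (OLS)",
                 f"  n = {self.nobs}, R2 = {self.rsquared:.3f}, "
                 f"F-test p = {self.f_pvalue:.3g}"]
        for name in self.params.index:
            lines.append(f"  {name:9s} {self.params[name]: .4f}"
                         f"  (p = {self.pvalues[name]:.3g})")
        return "\n".join(lines)


class EQTLModel:
    """One combination's design: z-scored expression on Mut/CNA/Purity/Tumour.

    Normal samples must already be coded Mut = 0, CNA = 2, Purity = 0,
    Tumour = 0 in the design frame.
    """

    VARIABLES = ("Mut", "CNA", "Purity", "Tumour")

    def __init__(self, design: pd.DataFrame):
        need = {"Exp", *self.VARIABLES}
        if not need.issubset(design.columns):
            raise ValueError(f"design needs columns {sorted(need)}")
        self.design = design

    @classmethod
    def from_matrices(cls, gene: str, locus: str, z: pd.DataFrame,
                      mut: pd.DataFrame, cna: pd.DataFrame,
                      purity: pd.Series, tumour: pd.Series) -> "EQTLModel":
        samples = z.columns
        design = pd.DataFrame({
            "Exp": z.loc[gene, samples],
            "Mut": mut.loc[locus, samples],
            "CNA": cna.loc[gene, samples],
            "Purity": purity[samples],
            "Tumour": tumour[samples].astype(float),
        })
        return cls(design)

    def fit(self, min_obs: int = 6) -> EQTLFit:
        d = self.design.dropna()
        if len(d) < min_obs:
            return EQTLFit(pd.Series(dtype=float), pd.Series(dtype=float),
                           np.nan, pd.DataFrame(), len(d),
                           np.nan, status="too few observations")
        x = sm.add_constant(d[list(self.VARIABLES)], has_constant="add")
        # drop constant predictors (keeps the fit full rank; noted in status)
        dropped = [v for v in self.VARIABLES if d[v].nunique() == 1]
        x = x.drop(columns=dropped)
        if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
            return EQTLFit(pd.Series(dtype=float), pd.Series(dtype=float),
                           np.nan, pd.DataFrame(), len(d),
                           np.nan, status="rank deficient")
        res = sm.OLS(d["Exp"], x).fit()
        status = "ok" if not dropped else \
            "dropped constant: " + ",".join(dropped)
        return EQTLFit(res.params, res.pvalues, float(res.f_pvalue),
                       res.conf_int(), int(res.nobs),
                       float(res.rsquared), status=status)


def fit_eqtl(design: pd.DataFrame, **kw) -> EQTLFit:
    """Functional wrapper: OLS of one combination's design frame."""
    return EQTLModel(design).fit(**kw)


def storey_pi0(pvalues, lambdas=None) -> float:
    """Storey's estimate of the proportion of true null hypotheses.

    Natural-cubic-smoother variant: pi0(lambda) evaluated on a grid and
    smoothed with a cubic spline, read off at the largest lambda; clipped
    to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no finite p-values")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    if len(lambdas) >= 4:
        from scipy.interpolate import UnivariateSpline
        spl = UnivariateSpline(lambdas, pi0_l, k=3)
        pi0 = float(spl(lambdas.max()))
    else:
        pi0 = float(pi0_l[-1])
    return float(np.clip(pi0, 0.0, 1.0))


def headline_percent(k: int, n: int) -> float:
    """A count ratio on the percentage scale used in headline reporting."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * k / n


class EQTLScreen:
    """Results of the cohort-wide screen.

    Attributes
    ----------
    table : DataFrame
        Per combination: coefficients, per-variable p, F p, FDR-adjusted
        values, flags.
    pi0 : float
        Storey's estimate of the true-null fraction of F-test p-values
        (1 - pi0 also reported: the convention the study quotes as
        "Storey's pi" is ambiguous, so both are carried).
    """

    def __init__(self, table: pd.DataFrame, pi0: float):
        self.table = table
        self.pi0 = pi0

    @property
    def pi(self) -> float:
        return 1.0 - self.pi0

    @property
    def n_explained(self) -> int:
        return int(self.table["explained"].sum())

    def explained_genes(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["explained"], "gene"].unique())

    def ratio_summary(self, n_genes_tested: int | None = None) -> dict:
        """Headline ratios: explained genes / tested genes, and per-variable
        significant counts, as percentages on the printed scale."""
        genes = self.table["gene"].nunique() if n_genes_tested is None \
            else n_genes_tested
        out = {"n_combinations": len(self.table),
               "n_genes": genes,
               "n_explained_genes": len(self.explained_genes()),
               "pct_explained_genes":
                   headline_percent(len(self.explained_genes()), genes)
                   if genes else np.nan}
        for v in EQTLModel.VARIABLES:
            out[f"n_sig_{v}"] = int(self.table[f"sig_{v}"].sum())
        return out

    def summary(self) -> str:
        r = self.ratio_summary()
        lines = [
            "Somatic eQTL screen",
            f"  combinations tested: {r['n_combinations']}",
            f"  genes: {r['n_genes']}",
            f"  explained genes (F FDR < 0.01): {r['n_explained_genes']} "
            f"({r['pct_explained_genes']:.1f}%)",
            f"  Storey pi0 = {self.pi0:.4f} (1 - pi0 = {self.pi:.4f})",
        ]
        for v in EQTLModel.VARIABLES:
            lines.append(f"  significant for {v}: {r[f'n_sig_{v}']}")
        return "\n".join(lines)


def screen(combos: pd.DataFrame, z: pd.DataFrame, mut: pd.DataFrame,
           cna: pd.DataFrame, purity: pd.Series, tumour: pd.Series,
           overall_fdr: float = 0.01, variable_fdr: float = 0.05
           ) -> EQTLScreen:
    """Fit every combination and apply the FDR rules.

    Benjamini-Hochberg on the F-test p (explained at < ``overall_fdr``) and
    on each coefficient's p (variable flags at < ``variable_fdr``);
    Storey's pi0 on the F-test p-values.
    """
    rows = []
    for combo in combos.itertuples(index=False):
        model = EQTLModel.from_matrices(combo.gene, combo.locus, z, mut,
                                        cna, purity, tumour)
        fit = model.fit()
        row = {"gene": combo.gene, "locus": combo.locus,
               "class": getattr(combo, "_2", None) or combo[2],
               "f_pvalue": fit.f_pvalue, "status": fit.status,
               "nobs": fit.nobs, "rsquared": fit.rsquared}
        for v in EQTLModel.VARIABLES:
            row[f"beta_{v}"] = fit.params.get(v, np.nan)
            row[f"p_{v}"] = fit.pvalues.get(v, np.nan)
        rows.append(row)
    tab = pd.DataFrame(rows)
    ok = tab["f_pvalue"].notna()
    if not ok.any():
        raise ValueError("no combination could be fitted")
    tab["f_fdr"] = np.nan
    tab.loc[ok, "f_fdr"] = multipletests(tab.loc[ok, "f_pvalue"],
                                         method="fdr_bh")[1]
    tab["explained"] = tab["f_fdr"] < overall_fdr
    for v in EQTLModel.VARIABLES:
        pv = tab[f"p_{v}"]
        okv = pv.notna()
        tab[f"fdr_{v}"] = np.nan
        if okv.any():
            tab.loc[okv, f"fdr_{v}"] = multipletests(pv[okv],
                                                     method="fdr_bh")[1]
        tab[f"sig_{v}"] = tab[f"fdr_{v}"] < variable_fdr
    pi0 = storey_pi0(tab.loc[ok, "f_pvalue"])
    return EQTLScreen(tab, pi0)


def classify_clonality(mut: pd.DataFrame, tumour_of: pd.Series
                       ) -> pd.Series:
    """Clonal vs subclonal per mutation locus.

    A locus is clonal iff, in every tumour carrying it, it is present in
    all of that tumour's matched samples; one partial tumour makes it
    subclonal.  Normal samples are ignored.
    """
    out = {}
    tumour_ids = [t for t in tumour_of.unique() if t != "normal"]
    groups = {t: tumour_of.index[tumour_of == t] for t in tumour_ids}
    for locus in mut.index:
        row = mut.loc[locus]
        clonal = True
        carried_anywhere = False
        for t, samples in groups.items():
            vals = row[samples]
            if vals.any():
                carried_anywhere = True
                if not vals.all():
                    clonal = False
                    break
        out[locus] = "clonal" if (clonal and carried_anywhere) else \
            ("subclonal" if carried_anywhere else "absent")
    return pd.Series(out, name="clonality")


def direction_test(n_up: int, n_down: int) -> float:
    """Two-sided test of up/down symmetry (proportion vs 0.5).

    Normal approximation without continuity correction, equivalent to the
    one-degree chi-square score test.
    """
    n = n_up + n_down
    if n == 0:
        raise ValueError("no observations")
    z = (n_up - n / 2.0) / np.sqrt(n / 4.0)
    return float(2.0 * stats.norm.sf(abs(z)))


def clonality_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion chi-square test with continuity correction
    (k1 of n1 versus k2 of n2)."""
    if min(n1, n2) == 0:
        raise ValueError("empty margin")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    return float(stats.chi2_contingency(table, correction=True).pvalue)


def enrichment_fisher(a: int, b: int, c: int, d: int
                      ) -> tuple[float, float, str]:
    """Sample odds ratio ad/bc and the exact two-sided Fisher p for the
    2x2 table [[a, b], [c, d]].  A zero cell triggers the Haldane 0.5
    correction for the reported OR (flagged)."""
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        return float(orr), p, "haldane 0.5 correction"
    return float(a * d / (b * c)), p, "ok"


def validate_external(beta_mut_discovery: float, exp2: pd.Series,
                      mut2: pd.Series, purity2: pd.Series,
                      alpha: float = 0.05) -> dict:
    """Replication in an external cohort via nested-model LRT.

    Fits Exp ~ Mut + Purity against Exp ~ Purity; validated iff the LRT p
    is below ``alpha`` and the Mut coefficient has the discovery sign.
    """
    mut2 = mut2.astype(float)
    if mut2.sum() < 1:
        return {"status": "untestable: no mutated samples",
                "validated": False, "p": np.nan, "beta_mut": np.nan}
    d = pd.DataFrame({"Exp": exp2, "Mut": mut2, "Purity": purity2}).dropna()
    full = sm.OLS(d["Exp"], sm.add_constant(d[["Mut", "Purity"]])).fit()
    null = sm.OLS(d["Exp"], sm.add_constant(d[["Purity"]])).fit()
    lrt = 2.0 * (full.llf - null.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    beta = float(full.params["Mut"])
    same_sign = np.sign(beta) == np.sign(beta_mut_discovery)
    return {"status": "ok", "validated": bool(p < alpha and same_sign),
            "p": p, "beta_mut": beta}


def required_n(effect: float, n2: int, power: float = 0.99,
               alpha: float = 0.05, inflation: float = 1.15,
               cap: float = 3.04) -> float:
    """Samples needed in group 1 to detect ``effect`` with a two-sample
    t-test at the given power, group 2 fixed at ``n2``.

    The absolute effect size is capped at 3.04 and the solved n1 is
    multiplied by 1.15 to allow for non-normality.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    d = min(abs(effect), cap)

    def power_at(n1):
        df = n1 + n2 - 2
        ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
        crit = stats.t.ppf(1 - alpha / 2, df)
        return stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)

    lo, hi = 2.0, 4.0
    while power_at(hi) < power and hi < 1e7:
        hi *= 2
    n1 = optimize.brentq(lambda n: power_at(n) - power, lo, hi, xtol=1e-6)
    return float(n1 * inflation)
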