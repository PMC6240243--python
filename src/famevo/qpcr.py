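"""RT-qPCR relative expression: 2^-ddCt, ANOVA and Fisher-LSD letters.

Ct tables carry one row per technical replicate with the target and
reference-gene (tubulin) cycle thresholds.  Technical replicates are
averaged into one Ct per biological replicate before anything else; per
replicate dCt = Ct_target - Ct_reference, ddCt = dCt - mean control dCt,
and relative expression is 2^-ddCt.  Statistics run on the log2 scale
(the ddCt values), where the Gaussian error model is natural, and group
means are back-transformed for reporting -- which makes the control
treatment's reported mean exactly 1 by construction.  Treatments are
compared per gene with a one-way ANOVA and all-pairs Fisher LSD at the
95% level, summarized as compact letter displays.  "N/D" (no detectable
expression) is a first-class state: excluded from the model, printed as
N/D, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "read_ct_table",
    "primer_efficiency",
    "average_technical_replicates",
    "ddct",
    "anova_lsd",
    "exclude_replicates",
    "RelativeExpression",
    "ExpressionResults",
]

CT_COLUMNS = [
    "gene",
    "treatment",
    "bio_rep",
    "tech_rep",
    "ct_target",
    "ct_reference",
    "detectable",
]


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with the canonical column set (see CT_COLUMNS)."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    return frame


def primer_efficiency(dilution_series) -> dict:
    """Amplification efficiency from a serial-dilution standard curve.

    ``dilution_series`` is a sequence of (log10 input amount, Ct) pairs.
    The least-squares slope of Ct on log10 input gives the amplification
    factor ``10 ** (-1 / slope)``; efficiency percent is (factor - 1)*100
    (a perfect doubling has slope -3.3219, factor 2, efficiency 100%).
    """
    pts = list(dilution_series)
    if len(pts) < 3:
        raise ValueError("at least 3 dilution points are required")
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    valid = slope < 0
    factor = 10.0 ** (-1.0 / slope) if valid else np.nan
    return {
        "slope": slope,
        "r_squared": float(fit.rvalue**2),
        "amplification_factor": factor,
        "efficiency_percent": (factor - 1.0) * 100.0 if valid else np.nan,
        "valid": valid,
    }


def average_technical_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """One row per (gene, treatment, biological replicate).

    A biological replicate is detectable only if all its technical
    replicates are.
    """
    grouped = records.groupby(["gene", "treatment", "bio_rep"], sort=False)
    out = grouped.agg(
        ct_target=("ct_target", "mean"),
        ct_reference=("ct_reference", "mean"),
        detectable=("detectable", "min"),
    ).reset_index()
    out["detectable"] = out["detectable"].astype(bool)
    return out


def exclude_replicates(records: pd.DataFrame, exclusions) -> pd.DataFrame:
    """Drop explicitly named biological replicates.

    ``exclusions`` is an iterable of (gene, treatment, bio_rep); ``gene``
    may be None to drop the replicate for every gene (e.g. a bad sample).
    There is deliberately no automatic outlier detection -- every removal
    is named by the caller and should be recorded in the run manifest.
    """
    out = records.copy()
    for gene, treatment, rep in exclusions:
        mask = (out["treatment"] == treatment) & (out["bio_rep"] == rep)
        if gene is not None:
            mask &= out["gene"] == gene
        if not mask.any():
            raise ValueError(
                f"no records match exclusion (gene={gene!r}, treatment={treatment!r}, bio_rep={rep!r})"
            )
        out = out[~mask]
    return out.reset_index(drop=True)


def ddct(records: pd.DataFrame, gene: str, control_treatment: str) -> pd.DataFrame:
    """Per-replicate ddCt and relative expression for one gene.

    ``records`` may contain technical replicates (they are averaged).
    Undetectable replicates propagate as N/D rows with NaN values.
    """
    sub = records[records["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no records for gene {gene!r}")
    bio = average_technical_replicates(sub)
    if bio["ct_reference"].isna().any():
        raise ValueError(f"missing reference Ct for gene {gene!r}")
    bio = bio.assign(dct=bio["ct_target"] - bio["ct_reference"])
    control = bio[(bio["treatment"] == control_treatment) & bio["detectable"]]
    if control.empty:
        raise ValueError(
            f"control treatment {control_treatment!r} has no detectable replicates for {gene!r}"
        )
    control_mean = float(control["dct"].mean())
    bio = bio.assign(ddct=bio["dct"] - control_mean)
    bio = bio.assign(rel_expr=np.power(2.0, -bio["ddct"]))
    bio.loc[~bio["detectable"], ["dct", "ddct", "rel_expr"]] = np.nan
    return bio


def _letters_from_significance(names, means, sig) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Start from one class holding every treatment; each significantly
    different pair splits the classes containing both; redundant
    (contained) classes are absorbed.  Treatments that do not differ are
    thereby guaranteed to share at least one letter, and treatments that
    differ never share one.  Letters are ordered by descending group mean
    so 'a' marks the highest-expressing group.
    """
    k = len(names)
    groups: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i][j]:
                continue
            new: list[set[int]] = []
            for g in groups:
                if i in g and j in g:
                    new.append(g - {i})
                    new.append(g - {j})
                else:
                    new.append(g)
            groups = [
                g
                for a, g in enumerate(new)
                if g and not any(a != b and g < h or (g == h and a > b) for b, h in enumerate(new))
            ]
    groups.sort(key=lambda g: -max(means[i] for i in g))
    letters = {i: "" for i in range(k)}
    for idx, group in enumerate(groups):
        ch = chr(ord("a") + idx)
        for i in group:
            letters[i] += ch
    return {names[i]: "".join(sorted(letters[i])) for i in range(k)}


def anova_lsd(values_by_treatment: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way ANOVA plus all-pairs Fisher LSD with letter groups.

    ``values_by_treatment`` maps treatment -> replicate values on the
    analysis (log2) scale, e.g. -ddCt.  Returns the ANOVA p-value, the
    pooled MSE and a
    compact letter display; treatments sharing no letter differ by more
    than their LSD at the chosen level.
    """
    names = [k for k, v in values_by_treatment.items() if len(v) > 0]
    groups = [np.asarray(values_by_treatment[k], float) for k in names]
    if len(names) < 2:
        return {"p_value": np.nan, "letters": {n: "a" for n in names}, "skipped": True}
    n_total = sum(len(g) for g in groups)
    df_error = n_total - len(groups)
    if df_error <= 0:
        return {"p_value": np.nan, "letters": {n: "a" for n in names}, "skipped": True}
    means = [float(g.mean()) for g in groups]
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / df_error
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    df_between = len(groups) - 1
    if mse == 0:
        p_value = 0.0 if ssb > 0 else 1.0
    else:
        f_stat = (ssb / df_between) / mse
        p_value = float(stats.f.sf(f_stat, df_between, df_error))
    t_crit = stats.t.ppf(1 - alpha / 2, df_error)
    k = len(groups)
    sig = [[False] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse == 0:
                different = diff > 0
            else:
                lsd = t_crit * np.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
                different = diff > lsd
            sig[i][j] = sig[j][i] = bool(different)
    letters = _letters_from_significance(names, means, sig)
    return {
        "p_value": p_value,
        "mse": float(mse),
        "df_error": int(df_error),
        "t_critical": float(t_crit),
        "letters": letters,
        "means": dict(zip(names, means)),
        "skipped": False,
    }


class RelativeExpression:
    """2^-ddCt expression model for a full gene x treatment Ct table.

    Parameters
    ----------
    records : Ct table (CT_COLUMNS schema), technical replicates included.
    control_treatment : the treatment every gene is normalized against.
    min_replicates : biological replicates required before statistics are
        attempted for a treatment (default 3).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        control_treatment: str,
        min_replicates: int = 3,
        exclusions=(),
    ):
        missing = set(CT_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if exclusions:
            records = exclude_replicates(records, exclusions)
        self.records = records
        self.control_treatment = control_treatment
        self.min_replicates = min_replicates
        self.exclusions = list(exclusions)

    def fit(self, alpha: float = 0.05) -> "ExpressionResults":
        genes = list(dict.fromkeys(self.records["gene"]))
        treatments = list(dict.fromkeys(self.records["treatment"]))
        per_gene: dict[str, pd.DataFrame] = {}
        anova: dict[str, dict] = {}
        table_rows = []
        for gene in genes:
            bio = ddct(self.records, gene, self.control_treatment)
            per_gene[gene] = bio
            values = {}
            flagged = set()
            for tr in treatments:
                # log2 relative expression (= -ddCt): the analysis scale
                vals = -bio.loc[
                    (bio["treatment"] == tr) & bio["detectable"], "ddct"
                ].to_numpy()
                if len(vals) >= self.min_replicates:
                    values[tr] = vals
                elif len(vals) > 0:
                    flagged.add(tr)
            res = anova_lsd(values, alpha=alpha)
            res["underpowered_treatments"] = sorted(flagged)
            anova[gene] = res
            for tr in treatments:
                sub = bio[bio["treatment"] == tr]
                n_det = int(sub["detectable"].sum())
                if n_det == 0:
                    status, mean_expr = "N/D", np.nan
                elif tr in flagged:
                    # detectable but too few replicates for statistics
                    status = "D"
                    mean_expr = float(2.0 ** -sub.loc[sub["detectable"], "ddct"].mean())
                else:
                    status = "ok"
                    mean_expr = float(2.0 ** -sub.loc[sub["detectable"], "ddct"].mean())
                table_rows.append(
                    {
                        "gene": gene,
                        "treatment": tr,
                        "rel_expr": mean_expr,
                        "status": status,
                        "letter": res["letters"].get(tr, ""),
                        "n_replicates": n_det,
                    }
                )
        return ExpressionResults(
            self, pd.DataFrame(table_rows), per_gene, anova, alpha=alpha
        )


class ExpressionResults:
    """Fitted expression analysis: per-gene tables, ANOVA, letter groups."""

    def __init__(self, spec, table: pd.DataFrame, per_gene, anova, alpha: float):
        self.spec = spec
        self.table = table
        self.per_gene = per_gene
        self.anova = anova
        self.alpha = alpha

    def expression_matrix(self) -> pd.DataFrame:
        """Genes x treatments table of "value letter" / N/D / D strings."""
        def fmt(row):
            if row["status"] == "N/D":
                return "N/D"
            if row["status"] == "D":
                return "D"
            s = f"{row['rel_expr']:.2f}"
            return f"{s} {row['letter']}" if row["letter"] else s

        out = self.table.assign(cell=self.table.apply(fmt, axis=1))
        return out.pivot(index="treatment", columns="gene", values="cell")

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for gene, res in self.anova.items():
            rows.append(
                {
                    "gene": gene,
                    "p_value": res.get("p_value", np.nan),
                    "mse": res.get("mse", np.nan),
                    "df_error": res.get("df_error", 0),
                    "skipped": res.get("skipped", False),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_genes = self.table["gene"].nunique()
        n_tr = self.table["treatment"].nunique()
        sig = sum(
            1
            for res in self.anova.values()
            if not res.get("skipped") and res.get("p_value", 1) <= self.alpha
        )
        lines = [
            "Relative expression (2^-ddCt) analysis",
            "=" * 40,
            f"genes:               {n_genes}",
            f"treatments:          {n_tr}",
            f"control treatment:   {self.spec.control_treatment}",
            f"genes with ANOVA p <= {self.alpha}: {sig}",
        ]
        return "\n".join(lines)
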