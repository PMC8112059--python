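"""Enhancer-activity quantification and three-class calling from STARR-seq counts.

The differential test is a self-contained negative-binomial Wald test:
median-of-ratios size factors, per-region method-of-moments dispersion
(floored, no trend shrinkage, poolable across replicate groups since the
NB dispersion is shared), and a Wald statistic on the log2 fold change
referred to a t distribution with the dispersion estimate's degrees of
freedom. The t reference (rather than a normal) compensates for the
noise of moment dispersion estimates at replicate counts of 3, which
would otherwise make the test anticonservative.

Classification rules (strict inequalities throughout):

* **inducible** — DHT/EtOH LFC > 1 and BH-adjusted p < 0.05;
* **constitutive** — plasmid-normalised LFC > 1 in both conditions and
  DHT/EtOH LFC < 1;
* **inactive** — plasmid-normalised LFC < 1 in both conditions;
* **ambiguous** — everything that satisfies no rule (the three published
  rules are not exhaustive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cutoffs of the three-class enhancer calling rules."""

    induced_lfc_min: float = 1.0
    induced_padj_max: float = 0.05
    active_plasmid_lfc_min: float = 1.0
    induction_lfc_ceiling_for_constitutive: float = 1.0
    inactive_plasmid_lfc_max: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.induced_padj_max < 1.0):
            raise ValueError("induced_padj_max must be in (0, 1)")
        for name in ("induced_lfc_min", "active_plasmid_lfc_min",
                     "induction_lfc_ceiling_for_constitutive",
                     "inactive_plasmid_lfc_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors, one per sample.

    For every region with all-positive counts, each sample's count is
    divided by the region's geometric mean; the factor is the median of
    those ratios over regions.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no region has positive counts in every sample; "
            "add a pseudocount before normalisation")
    logs = np.log(mat[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_moments(norm: np.ndarray, inv_sf: np.ndarray):
    """Per-region mean, sample variance and mean 1/s_j for one group."""
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    return mu, var, inv_sf.mean()


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    dispersion_groups: list[list[str]] | None = None,
) -> pd.DataFrame:
    """Wald test of differential activity between two sample groups.

    Returns a table indexed by region with ``lfc`` (log2 of normalised
    mean ratio b/a with pseudocount), ``se``, ``p`` (two-sided) and the
    moment dispersion estimate. ``group_b`` is the numerator (treatment).

    ``dispersion_groups`` lists replicate groups used for the per-region
    dispersion estimate (default: the two tested groups). The NB
    dispersion is shared across conditions, so including further
    replicate groups of the same experiment (e.g. the plasmid input)
    adds degrees of freedom without biasing the contrast; the Wald
    statistic is referred to a t distribution with the pooled
    dispersion's degrees of freedom.
    """
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        if len(grp) == 0:
            raise ValueError(f"{name} has no samples")
        if len(grp) < 2:
            raise ValueError(f"{name} needs >= 2 samples for a dispersion estimate")
    if dispersion_groups is None:
        dispersion_groups = [list(group_a), list(group_b)]
    all_samples = sorted({s for g in dispersion_groups for s in g}
                         | set(group_a) | set(group_b))
    if factors is None:
        factors = size_factors(counts[all_samples])
    sf = factors.reindex(all_samples)

    # method-of-moments NB dispersion on the normalised scale, pooled
    # across replicate groups: var(K/s) ~= mu * mean(1/s) + alpha * mu^2
    alpha = np.zeros(len(counts))
    df = 0
    for grp in dispersion_groups:
        norm_g = counts[grp].to_numpy(float) / sf[grp].to_numpy()
        mu_g, var_g, mean_inv_g = _group_moments(norm_g, 1.0 / sf[grp].to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = (var_g - mu_g * mean_inv_g) / np.square(mu_g)
        alpha += (len(grp) - 1) * np.nan_to_num(alpha_g)
        df += len(grp) - 1
    alpha = np.maximum(alpha / df, DISPERSION_FLOOR)

    norm_a = counts[group_a].to_numpy(float) / sf[group_a].to_numpy()
    norm_b = counts[group_b].to_numpy(float) / sf[group_b].to_numpy()
    mu_a, _, mean_inv_a = _group_moments(norm_a, 1.0 / sf[group_a].to_numpy())
    mu_b, _, mean_inv_b = _group_moments(norm_b, 1.0 / sf[group_b].to_numpy())
    n_a, n_b = len(group_a), len(group_b)

    lfc = np.log2(mu_b + pseudocount) - np.log2(mu_a + pseudocount)
    var_mu_a = (mu_a * mean_inv_a + alpha * np.square(mu_a)) / n_a
    var_mu_b = (mu_b * mean_inv_b + alpha * np.square(mu_b)) / n_b
    se = np.sqrt(var_mu_a / np.square(mu_a + pseudocount)
                 + var_mu_b / np.square(mu_b + pseudocount)) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(wald), df=df)
    p = np.where(se > 0, p, 1.0)
    return pd.DataFrame({"lfc": lfc, "se": se, "p": p, "dispersion": alpha},
                        index=counts.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def activity_stats(
    counts: pd.DataFrame,
    roles: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-region activity statistics from a count matrix + roles.

    Columns: ``lfc_dht_vs_etoh, se, p, padj, lfc_rna_plasmid_etoh,
    lfc_rna_plasmid_dht`` plus mean normalised counts per role. The
    DHT-vs-EtOH contrast is the NB Wald test; plasmid-normalised LFCs are
    log2 ratios of condition means to the plasmid mean (pseudocount on
    the normalised scale).
    """
    by_role = {role: roles.loc[roles["role"] == role, "sample"].tolist()
               for role in ("plasmid", "rna_etoh", "rna_dht")}
    for role, cols in by_role.items():
        if not cols:
            raise ValueError(f"no samples with role {role!r}")
    factors = size_factors(counts[[s for cols in by_role.values() for s in cols]])
    wald = nb_wald_test(counts, by_role["rna_etoh"], by_role["rna_dht"],
                        factors=factors, pseudocount=pseudocount,
                        dispersion_groups=list(by_role.values()))
    norm = counts / factors
    means = {role: norm[cols].mean(axis=1) for role, cols in by_role.items()}
    out = pd.DataFrame({
        "lfc_dht_vs_etoh": wald["lfc"],
        "se": wald["se"],
        "p": wald["p"],
        "padj": bh_adjust(wald["p"].to_numpy()),
        "lfc_rna_plasmid_etoh": np.log2(means["rna_etoh"] + pseudocount)
        - np.log2(means["plasmid"] + pseudocount),
        "lfc_rna_plasmid_dht": np.log2(means["rna_dht"] + pseudocount)
        - np.log2(means["plasmid"] + pseudocount),
        "mean_norm_plasmid": means["plasmid"],
        "mean_norm_rna_etoh": means["rna_etoh"],
        "mean_norm_rna_dht": means["rna_dht"],
    })
    return out


REQUIRED_STATS = ("lfc_dht_vs_etoh", "padj",
                  "lfc_rna_plasmid_etoh", "lfc_rna_plasmid_dht")


def classify_enhancers(
    stats: pd.DataFrame,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Assign each region to inducible / constitutive / inactive / ambiguous.

    A pure function of the statistics table and the thresholds; rules are
    applied in order with strict inequalities.
    """
    for col in REQUIRED_STATS:
        if col not in stats.columns:
            raise ValueError(f"missing statistic column {col!r}")
        bad = stats.index[stats[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col!r} for region {bad[0]!r}")
    th = thresholds
    ind = stats["lfc_dht_vs_etoh"].to_numpy()
    padj = stats["padj"].to_numpy()
    etoh = stats["lfc_rna_plasmid_etoh"].to_numpy()
    dht = stats["lfc_rna_plasmid_dht"].to_numpy()

    inducible = (ind > th.induced_lfc_min) & (padj < th.induced_padj_max)
    constitutive = (~inducible
                    & (etoh > th.active_plasmid_lfc_min)
                    & (dht > th.active_plasmid_lfc_min)
                    & (ind < th.induction_lfc_ceiling_for_constitutive))
    inactive = (~inducible & ~constitutive
                & (np.maximum(etoh, dht) < th.inactive_plasmid_lfc_max))
    label = np.select([inducible, constitutive, inactive],
                      ["inducible", "constitutive", "inactive"], "ambiguous")
    return pd.DataFrame({"enhancer_class": label}, index=stats.index)


def class_enrichment_test(
    region_scores: pd.DataFrame,
    calls: pd.Series,
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Rank-sum enrichment of per-sample z-scores between enhancer classes.

    Scores are z-transformed per sample column (correcting for total
    signal differences), summarised per region as the median z across
    samples, and compared between classes with a two-sided Mann-Whitney
    test; BH correction is applied across the requested comparisons.
    """
    z = (region_scores - region_scores.mean(axis=0)) / region_scores.std(axis=0, ddof=0)
    med = z.median(axis=1)
    calls = calls.reindex(med.index)
    rows = []
    for a, b in comparisons:
        xa = med[calls == a]
        xb = med[calls == b]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"class {a if len(xa) < 2 else b!r} has < 2 regions")
        u, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"class_a": a, "class_b": b, "n_a": len(xa), "n_b": len(xb),
                     "median_z_a": float(xa.median()), "median_z_b": float(xb.median()),
                     "u": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
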