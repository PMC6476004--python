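"""Differential-metabolite identification.

A spectral variable is called significant when its VIP exceeds 1 and the
absolute Pearson correlation of the variable with the predictive score
exceeds the critical value of the correlation coefficient at
df = min(n1, n2) - 1. Metabolites are quantified as the summed normalized
intensity over their non-overlapping signature windows; fold changes are
ratios of group means expressed >= 1 with a separate direction flag, and a
two-sided Mann-Whitney test provides the univariate star coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import LatentModel, correlation_loadings, vip
from .errors import DataError, DependencyError, QuantificationError
from .preprocess import BinnedMatrix
from .reference import COMPARISONS, MetaboliteReference

CLASS_VERY = "very_significant"
CLASS_SIG = "significant"
CLASS_NS = "NS"

#: comparison label -> (group treated as case, group treated as reference)
COMPARISON_GROUPS = {
    "polyp_vs_control": ("polyp", "control"),
    "crc_vs_control": ("crc", "control"),
    "crc_vs_polyp": ("crc", "polyp"),
}


def critical_r(n1: int, n2: int, alpha: float) -> float:
    """Critical two-tailed Pearson correlation at df = min(n1, n2) - 1.

    r_crit = t_c / sqrt(t_c^2 + df) where t_c is the two-tailed Student-t
    critical value at `alpha` with df degrees of freedom.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = min(int(n1), int(n2)) - 1
    if df < 2:
        raise ValueError(f"df = min(n1, n2) - 1 = {df} < 2")
    t_c = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_c / np.sqrt(t_c**2 + df))


def classify_variables(
    vip_scores, r, n1: int, n2: int, alphas: tuple[float, float] = (0.05, 0.01)
) -> np.ndarray:
    """Per-variable class from the VIP > 1 rule and |r| thresholds.

    very_significant: VIP > 1 and |r| > r_crit(alpha_strict);
    significant: VIP > 1 and r_crit(alpha_loose) < |r| <= r_crit(alpha_strict);
    NS otherwise. The VIP rule dominates: a variable with VIP <= 1 is NS
    regardless of |r|.
    """
    v = np.asarray(vip_scores, dtype=float)
    r = np.asarray(r, dtype=float)
    if v.shape != r.shape:
        raise DataError(f"vip and r are misaligned: {v.shape} vs {r.shape}")
    loose, strict = max(alphas), min(alphas)
    r_loose = critical_r(n1, n2, loose)
    r_strict = critical_r(n1, n2, strict)
    out = np.full(v.shape, CLASS_NS, dtype=object)
    absr = np.abs(r)
    out[(v > 1) & (absr > r_strict)] = CLASS_VERY
    out[(v > 1) & (absr > r_loose) & (absr <= r_strict)] = CLASS_SIG
    return out


def metabolite_windows(
    ref: MetaboliteReference, half_width: float = 0.01
) -> dict[str, list[tuple[float, float]]]:
    """Quantification windows (center +- half_width) per metabolite."""
    return {
        m.name: [(c - half_width, c + half_width) for c in m.quant_centers] for m in ref
    }


def quantify_metabolites(
    m: BinnedMatrix, ref: MetaboliteReference, half_width: float = 0.01
) -> pd.DataFrame:
    """Relative concentrations: summed normalized bin values per signature window.

    Requires a normalized matrix. A metabolite whose windows contain no
    active bin (e.g. fully inside the water mask) raises
    :class:`QuantificationError`.
    """
    if m.provenance.get("normalized") != "total_intensity":
        raise QuantificationError("matrix must be sum-normalized before quantification")
    centers = m.bin_centers
    table = {}
    for name, windows in metabolite_windows(ref, half_width).items():
        idx = np.zeros(m.n_bins, dtype=bool)
        for lo, hi in windows:
            idx |= (centers >= lo) & (centers < hi)
        idx &= ~m.excluded_mask
        if not idx.any():
            raise QuantificationError(
                f"metabolite {name!r}: no active bins in its signature windows"
            )
        table[name] = m.values[:, idx].sum(axis=1)
    df = pd.DataFrame(table, index=m.sample_ids)
    df.index.name = "sample_id"
    return df


def _stars(p: float) -> str:
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class SignificanceTable:
    """Long-format differential-metabolite table plus reporting helpers."""

    table: pd.DataFrame  # one row per metabolite x comparison
    thresholds: dict  # per comparison: n1, n2, df, r_crit at both alphas

    def significant_union(self) -> list[str]:
        """Metabolites significant (VIP>1 and |r| above threshold) in >= 1 comparison."""
        sig = self.table[self.table["class"] != CLASS_NS]
        return sorted(sig["metabolite"].unique().tolist())

    def to_wide(self) -> pd.DataFrame:
        """One row per metabolite, per-comparison VIP / |r| / change columns."""
        out = {}
        for comp, sub in self.table.groupby("comparison"):
            sub = sub.set_index("metabolite")
            arrow = sub["direction"].map({"up": "+", "down": "-", "none": "="})
            change = arrow + sub["stars"] + "/" + sub["fold_change"].map("{:.2f}".format)
            out[(comp, "VIP")] = sub["vip"].round(2)
            out[(comp, "|r|")] = sub["r"].abs().round(2)
            out[(comp, "change")] = change
        wide = pd.DataFrame(out)
        wide.index.name = "metabolite"
        return wide

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for comp, th in self.thresholds.items():
                fh.write(
                    f"# {comp}: n1={th['n1']} n2={th['n2']} df={th['df']} "
                    f"r_crit(0.05)={th['r_crit_0.05']:.3f} "
                    f"r_crit(0.01)={th['r_crit_0.01']:.3f}\n"
                )
            self.to_wide().to_csv(fh, sep="\t")


def differential_table(
    quant: pd.DataFrame,
    models: dict[str, LatentModel],
    binned: BinnedMatrix,
    ref: MetaboliteReference,
    half_width: float = 0.01,
    alphas: tuple[float, float] = (0.05, 0.01),
) -> SignificanceTable:
    """Aggregate bin-level VIP and correlation loadings to the metabolite level.

    For each pairwise comparison the fitted OPLS-DA model in `models`
    provides per-bin VIP and r; each metabolite is represented by the
    maximum-|r| bin inside its signature windows. Fold change is the ratio
    of group means of the quantified values, expressed >= 1 with the
    direction flag carrying orientation, and the univariate p-value is a
    two-sided Mann-Whitney test.
    """
    missing = [c for c in COMPARISONS if c not in models]
    if missing:
        raise DependencyError(f"missing fitted models for comparisons: {missing}")

    centers = binned.bin_centers
    active = binned.active_indices
    windows = metabolite_windows(ref, half_width)
    groups = np.asarray(binned.groups)
    sample_ids = np.asarray(binned.sample_ids)

    rows = []
    thresholds = {}
    for comp in COMPARISONS:
        case, base = COMPARISON_GROUPS[comp]
        model = models[comp]
        sel = np.isin(groups, (case, base))
        sub = binned.subset((case, base))
        vips = vip(model)
        corr = correlation_loadings(model, sub).r
        n_case = int((groups == case).sum())
        n_base = int((groups == base).sum())
        thresholds[comp] = {
            "n1": n_base,
            "n2": n_case,
            "df": min(n_base, n_case) - 1,
            "r_crit_0.05": critical_r(n_base, n_case, 0.05),
            "r_crit_0.01": critical_r(n_base, n_case, 0.01),
        }

        case_ids = sample_ids[sel][groups[sel] == case]
        base_ids = sample_ids[sel][groups[sel] == base]
        for met in ref:
            in_window = np.zeros(binned.n_bins, dtype=bool)
            for lo, hi in windows[met.name]:
                in_window |= (centers >= lo) & (centers < hi)
            # positions of the metabolite's bins within the active set
            pos = np.flatnonzero(in_window[active])
            if pos.size == 0:
                raise QuantificationError(
                    f"metabolite {met.name!r}: signature windows fully masked"
                )
            best = pos[np.argmax(np.abs(corr[pos]))]
            met_vip = float(vips[best])
            met_r = float(corr[best])

            q_case = quant.loc[case_ids, met.name].to_numpy()
            q_base = quant.loc[base_ids, met.name].to_numpy()
            mean_case, mean_base = q_case.mean(), q_base.mean()
            if mean_case >= mean_base:
                fold, direction = mean_case / mean_base, "up"
            else:
                fold, direction = mean_base / mean_case, "down"
            p_u = float(stats.mannwhitneyu(q_case, q_base, alternative="two-sided").pvalue)
            cls = classify_variables([met_vip], [met_r], n_base, n_case, alphas)[0]
            if cls == CLASS_NS:
                direction = "none"
            rows.append(
                {
                    "metabolite": met.name,
                    "comparison": comp,
                    "vip": met_vip,
                    "r": met_r,
                    "class": cls,
                    "fold_change": float(fold),
                    "direction": direction,
                    "p_univariate": p_u,
                    "stars": _stars(p_u),
                    "n1": n_base,
                    "n2": n_case,
                }
            )

    return SignificanceTable(table=pd.DataFrame(rows), thresholds=thresholds)
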