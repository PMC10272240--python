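"""Nonparametric inferential machinery for TRP tables.

Implements robust descriptives (median / median absolute deviation), a
Shapiro-Wilk normality annotation, factorial repeated-measures ANOVA on
Aligned-Rank-Transformed (ART) responses with partial eta squared, and
pairwise Wilcoxon signed-rank posthocs with Bonferroni correction and the
effect size r = |Z| / sqrt(n).

The ART procedure makes a factorial ANOVA applicable to data violating its
distributional assumptions: for each effect, the response is *aligned*
(stripped of every other effect by subtracting the full-factorial cell mean
and adding back the tested effect's marginal estimate), midrank-transformed
over all observations, and submitted to a univariate repeated-measures
ANOVA in which the subject is the random blocking unit and each effect is
tested against its subject-by-effect interaction stratum.  Only the
aligned-for effect is interpreted from each pass.

The model/results split follows common statistical-modelling practice:
``ArtAnova(data, dv, within, subject).fit()`` returns an
``ArtAnovaResults`` whose ``summary()`` prints the effect table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .montage import Montage, default_montage

__all__ = [
    "DescriptiveStats", "med_mad", "normality_check",
    "ArtAnova", "ArtAnovaResults", "art_transform", "art_anova",
    "WilcoxonResult", "wilcoxon_signed_rank", "bonferroni_adjust",
    "posthoc_decomposition",
]

MAD_SCALE = 1.4826  # consistency constant for the normal distribution


# ---------------------------------------------------------------------------
# descriptives

@dataclass(frozen=True)
class DescriptiveStats:
    med: float
    mad: float
    n: int


def med_mad(values: Sequence[float], scaled: bool = True) -> DescriptiveStats:
    """Median and median absolute deviation (x1.4826 when ``scaled``)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if scaled:
        mad *= MAD_SCALE
    return DescriptiveStats(med=med, mad=mad, n=int(x.size))


def normality_check(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W and p.  Annotation only — the pipeline stays nonparametric."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) input")
    w, p = _sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# aligned rank transform

def _factorize(col: pd.Series) -> Tuple[np.ndarray, List]:
    codes, uniques = pd.factorize(col, sort=True)
    return codes.astype(np.intp), list(uniques)


def _marginal_mean(y: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    sums = np.bincount(codes, weights=y, minlength=n_levels)
    counts = np.bincount(codes, minlength=n_levels)
    return sums / counts


def _effects(within: Sequence[str]) -> List[Tuple[str, ...]]:
    effs: List[Tuple[str, ...]] = [(f,) for f in within]
    effs += [tuple(c) for c in itertools.combinations(within, 2)]
    return effs


def _align(y: np.ndarray, codes: Mapping[str, np.ndarray],
           within: Sequence[str], levels: Mapping[str, int],
           effect: Tuple[str, ...], cell_grid: np.ndarray,
           cell_mean_obs: np.ndarray) -> np.ndarray:
    """Aligned response for one effect (pre-rank).

    Marginal estimates are unweighted means of the full-factorial cell
    means (least-squares means), so alignment strips every other effect
    even when cells hold unequal replicate counts.
    """
    axes = {f: i for i, f in enumerate(within)}
    grand = float(cell_grid.mean())
    if len(effect) == 1:
        f = effect[0]
        other = tuple(i for i in range(cell_grid.ndim) if i != axes[f])
        m = cell_grid.mean(axis=other) if other else cell_grid
        est = m[codes[f]] - grand
    else:
        a, b = effect
        other = tuple(i for i in range(cell_grid.ndim)
                      if i not in (axes[a], axes[b]))
        m_ab = cell_grid.mean(axis=other) if other else cell_grid
        if axes[a] > axes[b]:
            m_ab = m_ab.T
        m_a = m_ab.mean(axis=1)
        m_b = m_ab.mean(axis=0)
        est = (m_ab[codes[a], codes[b]] - m_a[codes[a]] - m_b[codes[b]]
               + grand)
    return y - cell_mean_obs + est


def _rm_anova_ranks(ranks: np.ndarray, subj: np.ndarray, n_subj: int,
                    codes: Mapping[str, np.ndarray],
                    levels: Mapping[str, int],
                    effect: Tuple[str, ...]) -> Tuple[float, int, int, float]:
    """Univariate repeated-measures F for one effect on its aligned ranks.

    Observations are first aggregated to subject x effect-cell means
    (collapsing replicate observations and any other factors); the effect
    is then tested against its subject-by-effect interaction stratum.  In a
    balanced design this equals the effect's row of the full univariate
    within-subject ANOVA.
    """
    if len(effect) == 1:
        a = codes[effect[0]]
        na = levels[effect[0]]
        cell = subj * na + a
        m = _marginal_mean(ranks, cell, n_subj * na).reshape(n_subj, na)
        grand = m.mean()
        ma = m.mean(axis=0)
        ms = m.mean(axis=1)
        ss_eff = n_subj * np.sum((ma - grand) ** 2)
        resid = m - ma[None, :] - ms[:, None] + grand
        ss_err = np.sum(resid ** 2)
        df1 = na - 1
        df2 = (na - 1) * (n_subj - 1)
    else:
        fa, fb = effect
        a, b = codes[fa], codes[fb]
        na, nb = levels[fa], levels[fb]
        cell = (subj * na + a) * nb + b
        m = _marginal_mean(ranks, cell, n_subj * na * nb).reshape(n_subj, na, nb)
        grand = m.mean()
        mab = m.mean(axis=0)                       # a x b
        ma = m.mean(axis=(0, 2))
        mb = m.mean(axis=(0, 1))
        msa = m.mean(axis=2)                       # s x a
        msb = m.mean(axis=1)                       # s x b
        ms = m.mean(axis=(1, 2))
        ss_eff = n_subj * np.sum(
            (mab - ma[:, None] - mb[None, :] + grand) ** 2)
        resid = (m - mab[None, :, :] - msa[:, :, None] - msb[:, None, :]
                 + ma[None, :, None] + mb[None, None, :] + ms[:, None, None]
                 - grand)
        ss_err = np.sum(resid ** 2)
        df1 = (na - 1) * (nb - 1)
        df2 = (na - 1) * (nb - 1) * (n_subj - 1)
    if ss_err <= 0:
        raise ZeroDivisionError("singular subject-by-effect error stratum")
    f_stat = (ss_eff / df1) / (ss_err / df2)
    return float(f_stat), df1, df2, float(_sps.f.sf(f_stat, df1, df2))


def _prepare(data: pd.DataFrame, dv: str, within: Sequence[str],
             subject: str):
    y = data[dv].to_numpy(dtype=float)
    subj, subj_levels = _factorize(data[subject])
    codes: Dict[str, np.ndarray] = {}
    levels: Dict[str, int] = {}
    level_names: Dict[str, List] = {}
    for f in within:
        codes[f], names = _factorize(data[f])
        levels[f] = len(names)
        level_names[f] = names
    # balance: every subject must populate every full-factorial cell with
    # the same count (cells may differ, e.g. 8 frontal vs 6 rear electrodes)
    fixed = np.zeros(len(y), dtype=np.intp)
    n_cells = 1
    for f in within:
        fixed = fixed * levels[f] + codes[f]
        n_cells *= levels[f]
    n_subj = len(subj_levels)
    counts = np.bincount(subj * n_cells + fixed,
                         minlength=n_subj * n_cells).reshape(n_subj, n_cells)
    if counts.min() < 1 or np.any(counts != counts[0]):
        raise ValueError("unbalanced design: every subject must hold the "
                         "same observations per factorial cell")
    # full-factorial (fixed-effects) cell means: per-cell grid + per-obs
    cell_means = _marginal_mean(y, fixed, n_cells)
    cell_grid = cell_means.reshape([levels[f] for f in within])
    cell_mean_obs = cell_means[fixed]
    return (y, subj, n_subj, codes, levels, level_names, cell_grid,
            cell_mean_obs)


def art_transform(data: pd.DataFrame, dv: str, within: Sequence[str],
                  subject: str = "subject") -> pd.DataFrame:
    """Aligned and midrank-transformed response columns, one pair per effect.

    Returns a copy of ``data`` with ``aligned(<effect>)`` and
    ``rank(<effect>)`` columns for every main effect and two-way interaction.
    """
    y, _subj, _ns, codes, levels, _names, grid, cmo = _prepare(
        data, dv, within, subject)
    out = data.copy()
    for eff in _effects(within):
        name = ":".join(eff)
        aligned = _align(y, codes, within, levels, eff, grid, cmo)
        out[f"aligned({name})"] = aligned
        out[f"rank({name})"] = _sps.rankdata(aligned)
    return out


class ArtAnova:
    """Nonparametric factorial repeated-measures ANOVA via aligned ranks.

    Parameters
    ----------
    data : long-format table, one row per observation.
    dv : response column (e.g. ``"trp"``).
    within : within-subject factors (e.g. ``["projection", "hemisphere"]``).
        All main effects and two-way interactions are tested.
    subject : column identifying the repeated-measures unit.
    """

    def __init__(self, data: pd.DataFrame, dv: str,
                 within: Sequence[str], subject: str = "subject") -> None:
        self.data = data.reset_index(drop=True)
        self.dv = dv
        self.within = list(within)
        self.subject = subject

    @classmethod
    def from_trp_table(cls, table: pd.DataFrame,
                       within: Sequence[str]) -> "ArtAnova":
        return cls(table, dv="trp", within=within, subject="subject")

    def fit(self) -> "ArtAnovaResults":
        y, subj, n_subj, codes, levels, names, grid, cmo = _prepare(
            self.data, self.dv, self.within, self.subject)
        rows = []
        for eff in _effects(self.within):
            aligned = _align(y, codes, self.within, levels, eff, grid, cmo)
            ranks = _sps.rankdata(aligned)
            f_stat, df1, df2, p = _rm_anova_ranks(
                ranks, subj, n_subj, codes, levels, eff)
            eta = f_stat * df1 / (f_stat * df1 + df2)
            rows.append({"effect": ":".join(eff), "F": f_stat,
                         "df_effect": df1, "df_error": df2, "p": p,
                         "eta_p_sq": eta})
        table = pd.DataFrame(rows)
        return ArtAnovaResults(model=self, anova_table=table,
                               n_subjects=n_subj, level_names=names)


@dataclass
class ArtAnovaResults:
    """Fitted ART ANOVA: per-effect F, degrees of freedom, p, partial eta²."""

    model: ArtAnova
    anova_table: pd.DataFrame
    n_subjects: int
    level_names: Dict[str, List]

    def significant_effects(self, alpha: float = 0.05) -> List[str]:
        t = self.anova_table
        return list(t.loc[t["p"] < alpha, "effect"])

    def effect(self, name: str) -> pd.Series:
        t = self.anova_table.set_index("effect")
        return t.loc[name]

    def summary(self) -> str:
        lines = ["Aligned-rank repeated-measures ANOVA",
                 f"  response: {self.model.dv}   subjects: {self.n_subjects}",
                 f"  within factors: {', '.join(self.model.within)}", ""]
        hdr = f"{'effect':<28}{'F':>10}{'df':>9}{'p':>12}{'eta_p^2':>10}"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for _, r in self.anova_table.iterrows():
            lines.append(
                f"{r['effect']:<28}{r['F']:>10.3f}"
                f"{int(r['df_effect']):>4},{int(r['df_error']):<4}"
                f"{r['p']:>12.3g}{r['eta_p_sq']:>10.4f}")
        return "\n".join(lines)


def art_anova(data: pd.DataFrame, dv: str, within: Sequence[str],
              subject: str = "subject") -> pd.DataFrame:
    """Convenience wrapper: fit an :class:`ArtAnova` and return its table."""
    return ArtAnova(data, dv, within, subject).fit().anova_table


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

@dataclass
class WilcoxonResult:
    V: float                  # sum of positive-difference ranks
    Z: float                  # normal-approximation statistic (tie/cc corrected)
    p: float
    r: float                  # effect size |Z| / sqrt(n_effective)
    n_effective: int
    p_adjusted: Optional[float] = None
    degenerate: bool = False


def _wilcoxon_z(v: float, ranks: np.ndarray) -> float:
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts ** 3 - tie_counts) / 48.0
    if sigma2 <= 0:
        return 0.0
    d = v - mu
    cc = 0.5 * np.sign(d)          # continuity correction toward the mean
    return float((d - cc) / math.sqrt(sigma2))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         exact_max_n: int = 25,
                         literal_r: bool = False) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; |differences| are midranked; V is the sum
    of ranks of positive differences.  The p-value is exact (full
    enumeration over sign assignments) for ``n <= exact_max_n`` without
    ties, otherwise the normal approximation with tie and continuity
    corrections.  Effect size ``r = |Z| / sqrt(n_effective)``;
    ``literal_r`` reports ``V / sqrt(n_effective)`` instead (a published
    but scale-dependent convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(V=0.0, Z=0.0, p=1.0, r=0.0, n_effective=0,
                              degenerate=True)
    ranks = _sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    z = _wilcoxon_z(v, ranks)
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        p = float(_sps.wilcoxon(d, alternative="two-sided",
                                method="exact").pvalue)
    else:
        p = float(_sps.wilcoxon(d, alternative="two-sided", correction=True,
                                method="approx").pvalue)
    stat = v if literal_r else abs(z)
    r = float(stat / math.sqrt(n))
    return WilcoxonResult(V=v, Z=z, p=p, r=r, n_effective=n)


def bonferroni_adjust(pvals: Sequence[float],
                      m: Optional[int] = None) -> List[float]:
    """Bonferroni: p_adj = min(1, m*p); ``m`` defaults to the family size."""
    p = list(pvals)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    for v in p:
        if not 0 <= v <= 1:
            raise ValueError(f"p-value {v} outside [0, 1]")
    return [min(1.0, m * v) for v in p]


# ---------------------------------------------------------------------------
# posthoc decomposition

def _paired(table: pd.DataFrame, contrast: str, level_a: str, level_b: str,
            match: Sequence[str],
            where: Optional[Mapping[str, str]] = None) -> Tuple[np.ndarray, np.ndarray]:
    t = table
    for col, val in (where or {}).items():
        t = t[t[col] == val]
    a = t[t[contrast] == level_a].set_index(list(match))["trp"]
    b = t[t[contrast] == level_b].set_index(list(match))["trp"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError(f"empty comparison family for {contrast} "
                         f"{level_a} vs {level_b}")
    return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def _with_pair_site(table: pd.DataFrame, montage: Montage) -> pd.DataFrame:
    site = {}
    for lh, rh in montage.homologous_pairs:
        site[lh] = f"{lh}|{rh}"
        site[rh] = f"{lh}|{rh}"
    t = table.copy()
    t["pair_site"] = t["electrode"].map(site)
    return t


def _area_means(table: pd.DataFrame) -> pd.DataFrame:
    # FA and RA hold unequal electrode counts; contrast per-subject area means
    return (table.groupby(["subject", "projection", "area"], as_index=False)
            ["trp"].mean())


def posthoc_decomposition(table: pd.DataFrame,
                          significant_effects: Sequence[str],
                          montage: Optional[Montage] = None,
                          mad_scaled: bool = True) -> pd.DataFrame:
    """Decompose significant ART effects into pairwise Wilcoxon families.

    ``table`` is a TRP table for one band and one task segment (columns
    subject, projection, electrode, hemisphere, area, trp).  For each
    significant main effect or interaction, the corresponding comparison
    families are run — projection within hemisphere/area/electrode,
    hemisphere (and the 7 homologous electrode pairs) within projection —
    each family Bonferroni-adjusted by its own comparison count.  Med/MAD
    are reported per contrasted cell.  Returns an empty frame when nothing
    is significant.
    """
    montage = montage or default_montage()
    sig = set(significant_effects)
    rows: List[dict] = []

    def add(family: str, scope: str, label: str, a: np.ndarray, b: np.ndarray):
        res = wilcoxon_signed_rank(a, b)
        da, db = med_mad(a, mad_scaled), med_mad(b, mad_scaled)
        rows.append({"family": family, "scope": scope, "comparison": label,
                     "med_a": da.med, "mad_a": da.mad,
                     "med_b": db.med, "mad_b": db.mad,
                     "n_pairs": res.n_effective, "V": res.V, "Z": res.Z,
                     "p": res.p, "r": res.r})

    tp = _with_pair_site(table, montage)

    if "projection" in sig:
        a, b = _paired(table, "projection", "orthographic", "isometric",
                       match=["subject", "electrode"])
        add("projection", "cortex", "orthographic vs isometric", a, b)

    if "hemisphere" in sig or "projection:hemisphere" in sig:
        for proj in ("orthographic", "isometric"):
            a, b = _paired(tp, "hemisphere", "LH", "RH",
                           match=["subject", "pair_site"],
                           where={"projection": proj})
            add("hemisphere_within_projection", proj, "LH vs RH", a, b)

    if "projection:hemisphere" in sig:
        for hemi in ("LH", "RH"):
            a, b = _paired(table, "projection", "orthographic", "isometric",
                           match=["subject", "electrode"],
                           where={"hemisphere": hemi})
            add("projection_within_hemisphere", hemi,
                "orthographic vs isometric", a, b)
        for proj in ("orthographic", "isometric"):
            for lh, rh in montage.homologous_pairs:
                sub = tp[tp["pair_site"] == f"{lh}|{rh}"]
                a, b = _paired(sub, "hemisphere", "LH", "RH",
                               match=["subject"], where={"projection": proj})
                add(f"pairs_within_{proj}", f"{lh}|{rh}", "LH vs RH", a, b)

    if "area" in sig or "projection:area" in sig:
        am = _area_means(table)
        for proj in ("orthographic", "isometric"):
            a, b = _paired(am.rename(columns={"trp": "trp"}), "area",
                           "FA", "RA", match=["subject"],
                           where={"projection": proj})
            add("area_within_projection", proj, "FA vs RA", a, b)

    if "projection:area" in sig:
        for area in ("FA", "RA"):
            a, b = _paired(table, "projection", "orthographic", "isometric",
                           match=["subject", "electrode"],
                           where={"area": area})
            add("projection_within_area", area,
                "orthographic vs isometric", a, b)

    if "projection:electrode" in sig or "electrode" in sig:
        for e in montage.electrodes:
            a, b = _paired(table, "projection", "orthographic", "isometric",
                           match=["subject"], where={"electrode": e})
            add("projection_within_electrode", e,
                "orthographic vs isometric", a, b)

    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["family", "scope", "comparison",
                                     "med_a", "mad_a", "med_b", "mad_b",
                                     "n_pairs", "V", "Z", "p", "p_adj", "r"])
    out["p_adj"] = np.nan
    for fam, grp in out.groupby("family"):
        out.loc[grp.index, "p_adj"] = bonferroni_adjust(grp["p"].tolist())
    return out
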