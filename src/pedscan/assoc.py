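"""Family-based association: measured-genotype (MG) and QTDT mixed models.

Genotype dosages are decomposed into a between-family component *b* and a
within-family component *w = g - b*, giving the fixed-effect model

    E[R] = mu + beta_b * b + beta_w * w

on top of polygenic (2*Phi*sigma2_a) and optional marker-specific linkage
(Pi*sigma2_qtl) variance components.  MG constrains beta_b = beta_w (a
single allelic slope, tested with a 1-df likelihood ratio); QTDT leaves
both free and tests beta_w = 0, which uses only within-family transmission
and is therefore robust to population stratification, at some cost in
power.  Including the linkage variance component at a marker absorbs
locus-specific familial correlation and helps control type I error when
linkage is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .ibd import IbdMatrix, MarkerGenotypes
from .mixedmodel import fit_ml
from .pedigree import KinshipMatrix, Pedigree

MAF_RARE_MAX = 0.01  # rare: maf < 1%
MAF_LOW_MAX = 0.05  # low-frequency: 1% <= maf < 5%; common: maf >= 5%

DEFAULT_MIN_N = 20


class AssocError(ValueError):
    pass


def classify_maf(maf: float) -> str:
    """MAF class: 'rare' (<1%), 'low' (1-5%), or 'common' (>=5%)."""
    if not 0.0 <= maf <= 0.5:
        raise AssocError(f"maf must lie in [0, 0.5], got {maf}")
    if maf < MAF_RARE_MAX:
        return "rare"
    if maf < MAF_LOW_MAX:
        return "low"
    return "common"


@dataclass
class GenotypeDecomposition:
    """Between/within-family split of dosages at one marker.

    ``table`` has one row per genotyped individual: columns id, g, b, w,
    cluster (the grouping used to form b: 'par' = parental mean, 'sib' =
    genotyped-sibship mean, 'self' = own genotype, w = 0).
    """

    marker_id: str
    table: pd.DataFrame

    @property
    def informative(self) -> bool:
        """True when some within-family genotype variance exists."""
        return bool(np.any(np.abs(self.table["w"].to_numpy()) > 1e-12))


def decompose_genotype(
    geno: MarkerGenotypes, peds: Sequence[Pedigree]
) -> GenotypeDecomposition:
    """Split each genotyped individual's dosage into b + w.

    b is the parental-mean dosage when both parents are genotyped, else the
    mean dosage of the individual's genotyped full sibship (self included),
    else the individual's own dosage (founders and genotype-isolated
    members, leaving w = 0).  Individuals with missing genotype are
    excluded from the marker.
    """
    rows = []
    any_typed = False
    for ped in peds:
        typed = {
            m.individual_id: geno.dosage(m.individual_id)
            for m in ped.members
            if geno.dosage(m.individual_id) is not None
        }
        if typed:
            any_typed = True
        # genotyped full sibships keyed by parent pair
        sib_sum: dict[tuple[str, str], list[float]] = {}
        for m in ped.members:
            if not m.is_founder and m.individual_id in typed:
                sib_sum.setdefault((m.father_id, m.mother_id), []).append(
                    typed[m.individual_id]
                )
        for m in ped.members:
            iid = m.individual_id
            if iid not in typed:
                continue
            g = float(typed[iid])
            if (
                not m.is_founder
                and m.father_id in typed
                and m.mother_id in typed
            ):
                b = 0.5 * (typed[m.father_id] + typed[m.mother_id])
                cluster = f"par:{ped.family_id}:{m.father_id}+{m.mother_id}"
            elif not m.is_founder:
                sibs = sib_sum[(m.father_id, m.mother_id)]
                b = float(np.mean(sibs))
                cluster = f"sib:{ped.family_id}:{m.father_id}+{m.mother_id}"
            else:
                b = g
                cluster = f"self:{ped.family_id}:{iid}"
            rows.append(
                {"id": iid, "g": g, "b": b, "w": g - b, "cluster": cluster}
            )
    if not any_typed:
        raise AssocError(
            f"marker {geno.marker_id!r}: no genotyped individuals; marker skipped"
        )
    return GenotypeDecomposition(geno.marker_id, pd.DataFrame(rows))


@dataclass
class AssocResult:
    """MG and QTDT association results at one marker."""

    marker_id: str
    position_bp: int = 0
    chromosome: str = ""
    maf: float | None = None
    maf_class: str | None = None
    beta_b: float = np.nan
    beta_w: float = np.nan
    beta_mg: float = np.nan
    p_mg: float = np.nan
    p_qtdt: float = np.nan
    linkage_vc_included: bool = False
    sigma2_qtl_at_marker: float | None = None
    loglik_mg_alt: float = np.nan
    loglik_qtdt_alt: float = np.nan
    n_used: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def informative(self) -> bool:
        return "noninformative" not in self.flags and "nonconverged" not in self.flags


def _assoc_blocks(
    R: pd.Series,
    kin: Mapping[str, KinshipMatrix],
    decomp: GenotypeDecomposition,
    columns: Sequence[str],
    ibd: Mapping[str, IbdMatrix] | None,
):
    tab = decomp.table.set_index("id")
    blocks = []
    n_used = 0
    for fam in sorted(kin):
        km = kin[fam]
        ids = [i for i in km.ids if i in R.index and i in tab.index]
        if not ids:
            continue
        n_used += len(ids)
        y = R.loc[ids].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(ids))] + [tab.loc[ids, c].to_numpy(float) for c in columns]
        )
        Vs = [km.subset(ids).matrix2]
        if ibd is not None:
            Vs.insert(0, ibd[fam].subset(ids).values)
        blocks.append((y, X, Vs))
    return blocks, n_used


def _lrt_p(ll_alt: float, ll_null: float) -> float:
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(max(chi2.sf(stat, 1), np.finfo(float).tiny))


def fit_mg(
    R,
    kin: Mapping[str, KinshipMatrix],
    decomp: GenotypeDecomposition,
    ibd_opt: Mapping[str, IbdMatrix] | None = None,
    min_n: int = DEFAULT_MIN_N,
    result: AssocResult | None = None,
) -> AssocResult:
    """Measured-genotype test: one slope for g = b + w, 1-df LRT of beta = 0.

    When ``ibd_opt`` is given, the marker's IBD matrix enters both the null
    and alternative model as a linkage variance component, so the test
    remains a pure fixed-effect contrast.
    """
    R = _series(R)
    res = result or AssocResult(decomp.marker_id)
    res.linkage_vc_included = ibd_opt is not None
    blocks, n_used = _assoc_blocks(R, kin, decomp, ["g"], ibd_opt)
    res.n_used = n_used
    if n_used < min_n:
        res.flags.append("too_few_individuals")
        return res
    g_all = np.concatenate([X[:, 1] for _, X, _ in blocks])
    if np.var(g_all) < 1e-12:
        res.flags.append("noninformative")
        return res
    null_blocks = [(y, X[:, :1], Vs) for y, X, Vs in blocks]
    try:
        null_fit = fit_ml(null_blocks, n_restarts=2)
        start = np.append(null_fit.variances[:-1], null_fit.variances[-1])
        alt_fit = fit_ml(blocks, start=start, n_restarts=1)
    except Exception:
        res.flags.append("nonconverged")
        return res
    ll_alt = max(alt_fit.loglik, null_fit.loglik)
    res.beta_mg = float(alt_fit.beta[1])
    res.loglik_mg_alt = ll_alt
    res.p_mg = _lrt_p(ll_alt, null_fit.loglik)
    if ibd_opt is not None:
        res.sigma2_qtl_at_marker = float(alt_fit.variances[0])
    return res


def fit_qtdt(
    R,
    kin: Mapping[str, KinshipMatrix],
    decomp: GenotypeDecomposition,
    ibd_opt: Mapping[str, IbdMatrix] | None = None,
    min_n: int = DEFAULT_MIN_N,
    result: AssocResult | None = None,
) -> AssocResult:
    """QTDT: beta_b and beta_w free, 1-df LRT of beta_w = 0."""
    R = _series(R)
    res = result or AssocResult(decomp.marker_id)
    res.linkage_vc_included = ibd_opt is not None
    if not decomp.informative:
        res.flags.append("noninformative")
        return res
    blocks, n_used = _assoc_blocks(R, kin, decomp, ["b", "w"], ibd_opt)
    res.n_used = n_used
    if n_used < min_n:
        res.flags.append("too_few_individuals")
        return res
    b_all = np.concatenate([X[:, 1] for _, X, _ in blocks])
    # degenerate clustering (e.g. all founders): b constant, drop it
    b_informative = np.var(b_all) > 1e-12
    if not b_informative:
        blocks = [(y, X[:, [0, 2]], Vs) for y, X, Vs in blocks]
    null_cols = [0, 1] if b_informative else [0]
    null_blocks = [(y, X[:, null_cols], Vs) for y, X, Vs in blocks] \
        if b_informative else [(y, X[:, :1], Vs) for y, X, Vs in blocks]
    try:
        null_fit = fit_ml(null_blocks, n_restarts=2)
        start = np.append(null_fit.variances[:-1], null_fit.variances[-1])
        alt_fit = fit_ml(blocks, start=start, n_restarts=1)
    except Exception:
        res.flags.append("nonconverged")
        return res
    ll_alt = max(alt_fit.loglik, null_fit.loglik)
    if b_informative:
        res.beta_b = float(alt_fit.beta[1])
        res.beta_w = float(alt_fit.beta[2])
    else:
        res.beta_w = float(alt_fit.beta[1])
    res.loglik_qtdt_alt = ll_alt
    res.p_qtdt = _lrt_p(ll_alt, null_fit.loglik)
    return res


def analyze_marker(
    R,
    kin: Mapping[str, KinshipMatrix],
    geno: MarkerGenotypes,
    peds: Sequence[Pedigree],
    ibd_opt: Mapping[str, IbdMatrix] | None = None,
    min_n: int = DEFAULT_MIN_N,
) -> AssocResult:
    """Run both MG and QTDT at one marker; one combined result row."""
    decomp = decompose_genotype(geno, peds)
    res = AssocResult(
        marker_id=geno.marker_id,
        position_bp=geno.position_bp,
        chromosome=geno.chromosome,
        maf=geno.maf,
        maf_class=classify_maf(geno.maf) if geno.maf is not None else None,
    )
    fit_mg(R, kin, decomp, ibd_opt, min_n, result=res)
    fit_qtdt(R, kin, decomp, ibd_opt, min_n, result=res)
    return res


def _series(R) -> pd.Series:
    if isinstance(R, pd.DataFrame):
        return R.set_index("id")["R"]
    return pd.Series(R)


def results_to_frame(results: Iterable[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": r.marker_id,
                "chr": r.chromosome,
                "bp": r.position_bp,
                "maf": r.maf,
                "maf_class": r.maf_class,
                "beta_b": r.beta_b,
                "beta_w": r.beta_w,
                "beta_mg": r.beta_mg,
                "p_mg": r.p_mg,
                "p_qtdt": r.p_qtdt,
                "linkage_vc": r.linkage_vc_included,
                "n_used": r.n_used,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


def qq_diagnostics(pvalues: Sequence[float], min_n: int = 100) -> dict:
    """Genomic inflation factor and expected-vs-observed -log10 p table.

    lambda is the median observed 1-df chi-square statistic divided by the
    null median (0.4549); lambda ~ 1 under the null, < 1 when p-values are
    deflated, > 1 under inflation (e.g. uncorrected stratification).
    """
    p = np.asarray([v for v in pvalues if np.isfinite(v)], float)
    if len(p) < min_n:
        raise AssocError(f"need >= {min_n} p-values for Q-Q diagnostics, got {len(p)}")
    if np.any((p <= 0) | (p > 1)):
        raise AssocError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, 1)
    lam = float(np.median(stats) / chi2.ppf(0.5, 1))
    n = len(p)
    obs = -np.log10(np.sort(p))  # descending -log10 p
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    table = pd.DataFrame(
        {"expected_neglog10p": exp, "observed_neglog10p": obs}
    )
    return {
        "lambda": lam,
        "n": n,
        "deflated": lam < 0.9,
        "inflated": lam > 1.1,
        "table": table,
    }


def plot_region(
    results: Sequence[AssocResult], path, which: str = "p_mg"
) -> None:
    """-log10 p by position, colored by MAF class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"rare": "red", "low": "green", "common": "blue"}
    fig, ax = plt.subplots(figsize=(9, 3))
    for cls, col in colors.items():
        xs = [r.position_bp / 1e6 for r in results if r.maf_class == cls]
        ys = [
            -np.log10(getattr(r, which))
            for r in results
            if r.maf_class == cls and np.isfinite(getattr(r, which))
        ]
        xs = xs[: len(ys)]
        ax.scatter(xs, ys, s=6, c=col, label=cls)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(f"-log10 {which}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
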