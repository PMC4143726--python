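"""Two-point variance-components linkage analysis.

For the adjusted phenotype R the phenotypic covariance of a pedigree is

    Sigma = Pi * sigma2_qtl + 2*Phi * sigma2_a + I * sigma2_e

where Pi holds marker-specific IBD sharing proportions and 2*Phi is twice
the kinship matrix.  The polygenic null model omits the QTL component; the
LOD score of a marker is log10 of the likelihood ratio of the two ML fits.
Markers are tested one at a time (two-point); no covariates enter here
because R is already covariate-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ibd import IbdMatrix, MarkerGenotypes
from .mixedmodel import fit_ml
from .pedigree import KinshipMatrix

LN10 = float(np.log(10.0))
DEFAULT_LOD_THRESHOLD = 1.2
DEFAULT_MERGE_BP = 10_000_000


class LinkageError(ValueError):
    pass


class MarkerSamplingError(LinkageError):
    pass


@dataclass
class PolygenicFit:
    """ML fit of the polygenic null model R ~ N(mu*1, 2*Phi*s2a + I*s2e)."""

    mu: float
    sigma2_a: float
    sigma2_e: float
    loglik: float
    converged: bool
    n_obs: int

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


@dataclass
class VcLinkageFit:
    """Two-point linkage result at one marker."""

    marker_id: str
    chromosome: str
    position_bp: int
    maf: float | None
    mu: float
    sigma2_qtl: float
    sigma2_a: float
    sigma2_e: float
    loglik_null: float
    loglik_alt: float
    lod: float
    confounded: bool = False  # Pi == 2*Phi: QTL variance unidentifiable


@dataclass
class LinkageRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    peak_marker_id: str
    peak_lod: float
    n_markers: int = 1


def _pheno_series(R) -> pd.Series:
    if isinstance(R, pd.DataFrame):
        return R.set_index("id")["R"]
    return pd.Series(R)


def _blocks(
    R: pd.Series,
    kin: Mapping[str, KinshipMatrix],
    ibd: Mapping[str, IbdMatrix] | None = None,
):
    """Per-pedigree (y, X=1, [structures]) blocks over phenotyped members."""
    blocks = []
    covered: set[str] = set()
    for fam in sorted(kin):
        km = kin[fam]
        ids = [i for i in km.ids if i in R.index]
        if not ids:
            continue
        covered.update(ids)
        y = R.loc[ids].to_numpy(float)
        X = np.ones((len(ids), 1))
        km_s = km.subset(ids)
        if ibd is None:
            blocks.append((y, X, [km_s.matrix2]))
        else:
            im = ibd[fam].subset(ids)
            blocks.append((y, X, [im.values, km_s.matrix2]))
    stray = set(R.index) - covered
    if stray:
        raise LinkageError(
            f"{len(stray)} phenotyped individuals not in any kinship matrix, "
            f"e.g. {sorted(stray)[:5]}"
        )
    if not blocks:
        raise LinkageError("no phenotyped pedigree members")
    return blocks


def fit_polygenic_null(
    R, kin: Mapping[str, KinshipMatrix], n_restarts: int = 3
) -> PolygenicFit:
    """ML polygenic model; the common null for every marker's linkage test."""
    R = _pheno_series(R)
    res = fit_ml(_blocks(R, kin), n_restarts=n_restarts)
    return PolygenicFit(
        mu=float(res.beta[0]),
        sigma2_a=float(res.variances[0]),
        sigma2_e=float(res.variances[1]),
        loglik=res.loglik,
        converged=res.converged,
        n_obs=res.n_obs,
    )


def fit_vc_linkage(
    R,
    kin: Mapping[str, KinshipMatrix],
    ibd: Mapping[str, IbdMatrix],
    null: PolygenicFit | None = None,
    marker: MarkerGenotypes | None = None,
    n_restarts: int = 2,
) -> VcLinkageFit:
    """Two-point VC linkage fit at one marker.

    ``ibd`` maps family to that marker's IBD matrix.  When Pi coincides
    with 2*Phi in every pedigree the QTL variance is confounded with the
    polygenic one; the fit is flagged and the LOD is 0 exactly.
    """
    R = _pheno_series(R)
    blocks = _blocks(R, kin, ibd)
    if null is None:
        null = fit_polygenic_null(R, kin, n_restarts=max(n_restarts, 3))
    mid = marker.marker_id if marker else next(iter(ibd.values())).marker_id
    chrom = marker.chromosome if marker else ""
    pos = marker.position_bp if marker else 0
    maf = marker.maf if marker else None

    confounded = all(
        np.abs(np.asarray(Vs[0]) - np.asarray(Vs[1])).max() < 1e-9
        for _, _, Vs in blocks
    )
    if confounded:
        return VcLinkageFit(
            mid, chrom, pos, maf, null.mu, 0.0, null.sigma2_a, null.sigma2_e,
            null.loglik, null.loglik, 0.0, confounded=True,
        )

    start = np.array([0.0, null.sigma2_a, null.sigma2_e])
    res = fit_ml(blocks, start=start, n_restarts=n_restarts)
    loglik_alt = max(res.loglik, null.loglik)  # alternative nests the null
    s2q = float(res.variances[0])
    at_boundary = bool(res.boundary[0]) or res.loglik <= null.loglik
    lod = 0.0 if at_boundary else max((loglik_alt - null.loglik) / LN10, 0.0)
    if at_boundary:
        s2q = 0.0
        loglik_alt = null.loglik
    return VcLinkageFit(
        marker_id=mid,
        chromosome=chrom,
        position_bp=pos,
        maf=maf,
        mu=float(res.beta[0]),
        sigma2_qtl=s2q,
        sigma2_a=float(res.variances[1]),
        sigma2_e=float(res.variances[2]),
        loglik_null=null.loglik,
        loglik_alt=loglik_alt,
        lod=lod,
        confounded=False,
    )


def sample_markers(
    markers: Sequence[MarkerGenotypes],
    n: int,
    maf_min: float = 0.05,
    exclude: Iterable[str] = (),
    seed: int = 0,
) -> list[MarkerGenotypes]:
    """Uniform sample of n common markers (MAF >= maf_min, inclusive),
    without replacement, excluding previously sampled marker ids."""
    excl = set(exclude)
    eligible = [
        m
        for m in markers
        if m.marker_id not in excl and m.maf is not None and m.maf >= maf_min
    ]
    if n > len(eligible):
        raise MarkerSamplingError(
            f"requested {n} markers but only {len(eligible)} eligible "
            f"(maf >= {maf_min}, {len(excl)} excluded)"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    picked = [eligible[i] for i in sorted(idx)]
    return picked


def select_regions(
    fits: Sequence[VcLinkageFit],
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    merge_bp: int = DEFAULT_MERGE_BP,
) -> list[LinkageRegion]:
    """Group markers exceeding the LOD threshold into linkage regions.

    The threshold is inclusive (lod >= threshold); qualifying markers on
    the same chromosome within ``merge_bp`` of each other share a region,
    and each region records its peak marker.
    """
    regions: list[LinkageRegion] = []
    by_chrom: dict[str, list[VcLinkageFit]] = {}
    for f in fits:
        if f.lod >= lod_threshold:
            by_chrom.setdefault(f.chromosome, []).append(f)
    for chrom in sorted(by_chrom):
        hits = sorted(by_chrom[chrom], key=lambda f: f.position_bp)
        group = [hits[0]]
        for f in hits[1:]:
            if f.position_bp - group[-1].position_bp <= merge_bp:
                group.append(f)
            else:
                regions.append(_region_from(chrom, group))
                group = [f]
        regions.append(_region_from(chrom, group))
    return regions


def _region_from(chrom: str, group: list[VcLinkageFit]) -> LinkageRegion:
    peak = max(group, key=lambda f: f.lod)
    return LinkageRegion(
        chromosome=chrom,
        start_bp=group[0].position_bp,
        end_bp=group[-1].position_bp,
        peak_marker_id=peak.marker_id,
        peak_lod=peak.lod,
        n_markers=len(group),
    )


def fits_to_frame(fits: Sequence[VcLinkageFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": f.marker_id,
                "chr": f.chromosome,
                "bp": f.position_bp,
                "maf": f.maf,
                "sigma2_qtl": f.sigma2_qtl,
                "sigma2_a": f.sigma2_a,
                "sigma2_e": f.sigma2_e,
                "lod": f.lod,
                "confounded": f.confounded,
            }
            for f in fits
        ]
    )


def regions_to_frame(regions: Sequence[LinkageRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chr": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "peak_marker": r.peak_marker_id,
                "peak_lod": r.peak_lod,
                "n_markers": r.n_markers,
            }
            for r in regions
        ],
        columns=["chr", "start_bp", "end_bp", "peak_marker", "peak_lod", "n_markers"],
    )


def plot_lod_profile(
    fits: Sequence[VcLinkageFit], path: str | Path, threshold: float | None = None
) -> None:
    """LOD-by-position profile plot (one panel per chromosome)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = fits_to_frame(fits)
    chroms = sorted(df["chr"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.8 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = df[df["chr"] == chrom].sort_values("bp")
        ax.plot(sub["bp"] / 1e6, sub["lod"], ".-", ms=3, lw=0.6)
        if threshold is not None:
            ax.axhline(threshold, color="gray", lw=0.8, ls="--")
        ax.set_xlabel(f"chr{chrom} position (Mb)")
        ax.set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
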