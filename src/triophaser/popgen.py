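"""Population-genetic statistics over a phased haplotype panel.

Inputs are an ``n`` haplotypes x ``m`` biallelic sites 0/1 indicator
matrix (−1 for missing) with 1-based positions and per-site annotation
(synonymous / nonsynonymous / noncoding, indel flag).  Implemented:

* folded site frequency spectrum;
* nucleotide diversity π and Tajima's D in sliding windows (standard
  1989 constants a1, a2, b1, b2, c1, c2, e1, e2);
* SNV/indel densities in sliding windows;
* windowed pN/pS with fixed nonsynonymous/synonymous site fractions
  (0.73 / 0.27 by default);
* minor-allele frequency as a function of distance to the nearest
  "classical" locus, with a linear regression on the nonbinned data and
  25-variant reporting bins;
* LD decay: haplotype r² between focal-locus SNPs and all other SNPs,
  arithmetic mean in 10-kb distance bins (MAF >= 0.05).

Missing genotypes are excluded pairwise for π and r²; windows with fewer
than three segregating sites leave Tajima's D undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import Interval

MIN_SEGREGATING_FOR_D = 3


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype matrix with site annotation."""

    genotypes: np.ndarray  # (n_haplotypes, n_sites), int8 in {0,1,-1}
    positions: np.ndarray  # 1-based, strictly increasing
    site_class: np.ndarray  # str per site
    is_indel: np.ndarray  # bool per site
    names: list[str]

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.site_class = np.asarray(self.site_class, dtype=object)
        self.is_indel = np.asarray(self.is_indel, dtype=bool)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        if self.genotypes.shape[0] < 2:
            raise ValueError("panel needs at least two haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per site (missing excluded)."""
        valid = self.genotypes >= 0
        alt = np.where(valid, self.genotypes, 0).sum(axis=0)
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = alt / n
        return np.minimum(f, 1 - f)

    @classmethod
    def from_founder_panel(cls, panel) -> "HaplotypePanel":
        """Build from a :class:`triophaser.simdata.FounderPanel`."""
        n = panel.n_haplotypes
        m = len(panel.variants)
        g = np.zeros((n, m), dtype=np.int8)
        for j, v in enumerate(panel.variants):
            for c in v.carriers:
                g[c, j] = 1
        return cls(
            genotypes=g,
            positions=np.array([v.pos + 1 for v in panel.variants]),
            site_class=np.array([v.site_class for v in panel.variants], dtype=object),
            is_indel=np.array([v.is_indel for v in panel.variants]),
            names=list(panel.names),
        )

    @classmethod
    def from_vcf(cls, path) -> "HaplotypePanel":
        """Read a phased VCF (diploid ``|``-separated or haploid GT)."""
        from cyvcf2 import VCF

        reader = VCF(str(path))
        samples = reader.samples
        rows: list[list[int]] = []
        positions: list[int] = []
        classes: list[str] = []
        indels: list[bool] = []
        ploidy = 1
        for var in reader:
            positions.append(var.POS)
            classes.append(var.INFO.get("SCLASS") or "other")
            indels.append(len(var.REF) != len(var.ALT[0]) if var.ALT else False)
            site: list[int] = []
            for gt in var.genotypes:
                alleles = gt[:-1]  # trailing element is the phased flag
                ploidy = max(ploidy, len(alleles))
                site.extend(-1 if a < 0 else int(a) for a in alleles)
            rows.append(site)
        g = np.array(rows, dtype=np.int8).T
        names = [
            f"{s}_h{k+1}" if ploidy > 1 else s
            for s in samples
            for k in range(ploidy)
        ]
        return cls(
            genotypes=g,
            positions=np.array(positions),
            site_class=np.array(classes, dtype=object),
            is_indel=np.array(indels),
            names=names,
        )


# ---------------------------------------------------------------------------
# Folded SFS


def folded_sfs(panel: HaplotypePanel) -> tuple[np.ndarray, int]:
    """Folded site frequency spectrum.

    Returns (counts, n_monomorphic): ``counts[i]`` is the number of sites
    whose minor allele count is ``i`` (i from 0 to n//2); monomorphic
    sites are dropped and reported.
    """
    valid = panel.genotypes >= 0
    alt = np.where(valid, panel.genotypes, 0).sum(axis=0)
    n = valid.sum(axis=0)
    minor = np.minimum(alt, n - alt)
    poly = minor > 0
    counts = np.bincount(minor[poly], minlength=panel.n_haplotypes // 2 + 1)
    return counts, int((~poly).sum())


# ---------------------------------------------------------------------------
# Diversity and Tajima's D


def tajimas_d_constants(n: int) -> dict[str, float]:
    """The standard constants of the D statistic for sample size n."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _per_site_pair_stats(panel: HaplotypePanel):
    """Per-site mean pairwise difference (missing excluded pairwise)."""
    valid = panel.genotypes >= 0
    alt = np.where(valid, panel.genotypes, 0).sum(axis=0)
    n = valid.sum(axis=0)
    pairs = n * (n - 1) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(pairs > 0, alt * (n - alt) / pairs, 0.0)
    segregating = (alt > 0) & (alt < n)
    return site_pi, segregating


def windowed_pi_d(
    panel: HaplotypePanel,
    window: int = 5_000,
    step: int = 1_000,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """π and Tajima's D in sliding windows.

    π is the mean pairwise difference per bp; D is
    ``(k − S/a1) / sqrt(e1·S + e2·S·(S−1))`` with the standard constants,
    undefined (NaN) in windows with fewer than three segregating sites.
    """
    if window < step:
        raise ValueError("window must be >= step")
    site_pi, segregating = _per_site_pair_stats(panel)
    const = tajimas_d_constants(panel.n_haplotypes)
    if region is None:
        region = (1, int(panel.positions[-1]) if panel.n_sites else window)
    start0, end0 = region
    rows = []
    pos = panel.positions
    for ws in range(start0, max(start0 + 1, end0 - window + 2), step):
        we = ws + window
        lo, hi = np.searchsorted(pos, [ws, we])
        idx = slice(lo, hi)
        S = int(segregating[idx].sum())
        k = float(site_pi[idx].sum())
        pi = k / window
        if S >= MIN_SEGREGATING_FOR_D:
            var = const["e1"] * S + const["e2"] * S * (S - 1)
            d = (k - S / const["a1"]) / np.sqrt(var)
        else:
            d = np.nan
        rows.append(
            dict(start=ws, end=we, pi=pi, tajima_d=d, n_sites=int(hi - lo), n_seg=S)
        )
    return pd.DataFrame(rows)


def variant_density(
    panel: HaplotypePanel,
    window: int = 50_000,
    step: int = 10_000,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """SNV and indel counts in sliding windows."""
    if region is None:
        region = (1, int(panel.positions[-1]) if panel.n_sites else window)
    start0, end0 = region
    rows = []
    pos = panel.positions
    for ws in range(start0, max(start0 + 1, end0 - window + 2), step):
        we = ws + window
        lo, hi = np.searchsorted(pos, [ws, we])
        ind = panel.is_indel[lo:hi]
        rows.append(
            dict(
                start=ws,
                end=we,
                snv_count=int((~ind).sum()),
                indel_count=int(ind.sum()),
            )
        )
    return pd.DataFrame(rows)


def pnps(
    panel: HaplotypePanel,
    frac_nonsyn: float = 0.73,
    frac_syn: float = 0.27,
    window: int = 50_000,
    step: int | None = None,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Windowed pN/pS with fixed nonsynonymous/synonymous site fractions.

    pN/pS = (nonsyn count / frac_nonsyn) / (syn count / frac_syn); windows
    without synonymous variants are flagged undefined (NaN).
    """
    if abs(frac_nonsyn + frac_syn - 1) > 1e-9:
        raise ValueError("site fractions must sum to 1")
    step = step or window
    if region is None:
        region = (1, int(panel.positions[-1]) if panel.n_sites else window)
    start0, end0 = region
    pos = panel.positions
    nonsyn = panel.site_class == "nonsynonymous"
    syn = panel.site_class == "synonymous"
    rows = []
    for ws in range(start0, max(start0 + 1, end0 - window + 2), step):
        we = ws + window
        lo, hi = np.searchsorted(pos, [ws, we])
        n_count = int(nonsyn[lo:hi].sum())
        s_count = int(syn[lo:hi].sum())
        if s_count == 0:
            ratio = np.nan
        else:
            ratio = (n_count / frac_nonsyn) / (s_count / frac_syn)
        rows.append(
            dict(start=ws, end=we, pnps=ratio, n_nonsyn=n_count, n_syn=s_count)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linked selection: MAF vs distance


def distance_to_intervals(positions: np.ndarray, intervals: Sequence[Interval]) -> np.ndarray:
    """bp distance (1-based positions) to the nearest interval edge; 0 inside."""
    pos0 = np.asarray(positions) - 1  # back to 0-based
    d = np.full(len(pos0), np.inf)
    for iv in intervals:
        inside = (pos0 >= iv.start) & (pos0 < iv.end)
        dist = np.where(
            inside, 0, np.maximum(iv.start - pos0, pos0 - (iv.end - 1))
        )
        d = np.minimum(d, dist)
    return d


def maf_vs_distance(
    panel: HaplotypePanel,
    classical: Sequence[Interval],
    classes: Sequence[str] = ("synonymous", "nonsynonymous"),
    bin_size: int = 25,
) -> dict[str, dict]:
    """MAF as a function of distance to the nearest classical locus.

    Variants inside classical intervals are excluded.  The linear
    regression (slope per bp) is fitted on the nonbinned data; bins of
    ``bin_size`` variants, ordered by distance, are reported for
    visualization (the final partial bin is dropped).
    """
    if not classical:
        raise ValueError("need at least one classical interval")
    maf = panel.maf()
    dist = distance_to_intervals(panel.positions, classical)
    outside = dist > 0
    results: dict[str, dict] = {}
    for cls in classes:
        sel = outside & (panel.site_class == cls)
        d, f = dist[sel], maf[sel]
        if len(d) >= 3 and np.ptp(d) == 0:
            # all variants equidistant: no trend by construction
            regression = dict(slope=0.0, intercept=float(f.mean()), pvalue=1.0, n=len(d))
        elif len(d) >= 3:
            reg = stats.linregress(d, f)
            regression = dict(
                slope=reg.slope, intercept=reg.intercept, pvalue=reg.pvalue, n=len(d)
            )
        else:
            regression = dict(slope=np.nan, intercept=np.nan, pvalue=np.nan, n=len(d))
        order = np.argsort(d, kind="stable")
        d_sorted, f_sorted = d[order], f[order]
        n_bins = len(d_sorted) // bin_size
        bins = pd.DataFrame(
            dict(
                mean_distance=[
                    d_sorted[i * bin_size : (i + 1) * bin_size].mean()
                    for i in range(n_bins)
                ],
                mean_maf=[
                    f_sorted[i * bin_size : (i + 1) * bin_size].mean()
                    for i in range(n_bins)
                ],
                n=[bin_size] * n_bins,
            )
        )
        results[cls] = dict(regression=regression, bins=bins)
    return results


# ---------------------------------------------------------------------------
# LD decay


def r_squared(panel: HaplotypePanel, i: int, j: int) -> float:
    """Haplotype r² between two sites (missing excluded pairwise)."""
    gi, gj = panel.genotypes[:, i], panel.genotypes[:, j]
    ok = (gi >= 0) & (gj >= 0)
    gi, gj = gi[ok].astype(float), gj[ok].astype(float)
    pa, pb = gi.mean(), gj.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    pab = np.mean(gi * gj)
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def ld_decay(
    panel: HaplotypePanel,
    focal_genes: Sequence[Interval],
    maf_min: float = 0.05,
    bin_bp: int = 10_000,
    max_distance: int | None = None,
) -> pd.DataFrame:
    """r² between focal-locus SNPs and all other SNPs vs distance.

    SNPs (indels excluded) with MAF >= ``maf_min`` participate; each
    (focal, other) pair contributes at its bp distance, and pairwise r²
    values are summarized per ``bin_bp`` bin by the arithmetic mean.
    """
    maf = panel.maf()
    usable = (~panel.is_indel) & (maf >= maf_min)
    dist_f = distance_to_intervals(panel.positions, focal_genes)
    focal_idx = np.flatnonzero(usable & (dist_f == 0))
    other_idx = np.flatnonzero(usable & (dist_f > 0))
    if len(focal_idx) == 0 or len(other_idx) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])

    g = panel.genotypes.astype(float)
    g[panel.genotypes < 0] = np.nan
    gf = g[:, focal_idx]
    go = g[:, other_idx]
    # complete-case vectorized path; per-pair fallback when data are missing
    if np.isnan(g).any():
        r2 = np.empty((len(focal_idx), len(other_idx)))
        for a, fi in enumerate(focal_idx):
            for b, oi in enumerate(other_idx):
                r2[a, b] = r_squared(panel, fi, oi)
    else:
        pf = gf.mean(axis=0)
        po = go.mean(axis=0)
        pfo = gf.T @ go / g.shape[0]
        num = (pfo - np.outer(pf, po)) ** 2
        den = np.outer(pf * (1 - pf), po * (1 - po))
        r2 = num / den

    dmat = np.abs(
        panel.positions[focal_idx][:, None] - panel.positions[other_idx][None, :]
    )
    dist = dmat.ravel()
    vals = r2.ravel()
    keep = ~np.isnan(vals)
    if max_distance is not None:
        keep &= dist <= max_distance
    dist, vals = dist[keep], vals[keep]
    bins = dist // bin_bp
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(
            dict(
                bin_start=int(b * bin_bp),
                bin_end=int((b + 1) * bin_bp),
                mean_r2=float(vals[sel].mean()),
                n_pairs=int(sel.sum()),
            )
        )
    return pd.DataFrame(rows)
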