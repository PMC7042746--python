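"""Per-SNP population-genetic statistics.

The statistics implemented here summarise, for every biallelic SNP of a
two-population cohort embedded in a wider panel:

* alternate-allele frequencies in each focal population,
* AFD, the absolute allele frequency differentiation |f_A - f_B|,
* windowed linkage disequilibrium, the mean squared Pearson correlation
  (r-squared) between a SNP's dosage vector and every neighbouring SNP
  within a fixed physical window,
* derived allele frequency (DAF), polarised by a probabilistic ancestral
  state call and left missing when the call is unreliable,
* the AFD.LD candidate rule: a SNP is a candidate for local adaptation when
  both its AFD and its focal-pair mean r-squared exceed high genome-wide
  percentiles (default the 95th, historically the values 0.70 and 0.19),
* a sliding-window scan of the fraction of SNPs satisfying a predicate.

Frequencies, r-squared and DAF are all in [0, 1]; NaN marks "missing".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PopulationMap

__all__ = [
    "allele_freq",
    "panel_alt_freq",
    "afd",
    "maf_filter",
    "snp_mean_r2",
    "daf",
    "daf_spectrum",
    "call_afd_ld_candidates",
    "CandidateCall",
    "window_scan",
    "build_variant_table",
]


# ---------------------------------------------------------------------------
# allele frequencies and AFD
# ---------------------------------------------------------------------------

def _freq_from_dosage(dosage: np.ndarray, ploidy: int) -> np.ndarray:
    """Alt-allele frequency per row; NaN where every dosage is missing."""
    present = ~np.isnan(dosage)
    n = present.sum(axis=1)
    total = np.nansum(dosage, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = total / (ploidy * n)
    f[n == 0] = np.nan
    return f


def allele_freq(matrix: GenotypeMatrix, popmap: PopulationMap, pop: str) -> np.ndarray:
    """Alt-allele frequency per SNP over the samples of one population."""
    idx = matrix.sample_indices(popmap.samples_in(pop))
    return _freq_from_dosage(matrix.dosage[:, idx], matrix.ploidy)


def panel_alt_freq(matrix: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per SNP over the entire panel."""
    return _freq_from_dosage(matrix.dosage, matrix.ploidy)


def afd(f_a: np.ndarray, f_b: np.ndarray) -> np.ndarray:
    """Absolute allele frequency differentiation |f_A - f_B| per SNP."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_a.shape != f_b.shape:
        raise ValueError("frequency columns are not aligned")
    return np.abs(f_a - f_b)


def maf_filter(matrix: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs whose panel minor allele frequency strictly exceeds ``threshold``."""
    f = panel_alt_freq(matrix)
    maf = np.minimum(f, 1.0 - f)
    keep = np.where(maf > threshold)[0]
    return matrix.take(keep)


# ---------------------------------------------------------------------------
# windowed LD
# ---------------------------------------------------------------------------

def snp_mean_r2(
    matrix: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    window_bp: int = 20_000,
    neighbor_mode: str = "distance",
    block_size: int = 512,
) -> np.ndarray:
    """Mean pairwise r-squared between each SNP and its window neighbours.

    Neighbours are same-chromosome SNPs within ``window_bp`` base pairs
    (``neighbor_mode="distance"``, the default) or within ``window_bp / 2``
    (``neighbor_mode="centered"``, a window of total span ``window_bp``),
    excluding the SNP itself.  Each pairwise r-squared is the squared Pearson
    correlation of the two dosage vectors over their pairwise-complete
    samples; pairs with fewer than two shared samples or zero variance on
    either side are undefined and contribute nothing to the mean.  A SNP with
    no defined pair gets NaN.

    The computation is blocked matrix algebra over sums of dosages and
    dosage products, so missing data is handled exactly without per-pair
    Python loops.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if neighbor_mode == "distance":
        radius = window_bp
    elif neighbor_mode == "centered":
        radius = window_bp // 2
    else:
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")

    X_all = matrix.dosage if sample_idx is None else matrix.dosage[:, sample_idx]
    out = np.full(matrix.n_variants, np.nan)
    for chrom in pd.unique(matrix.chrom):
        rows = np.where(matrix.chrom == chrom)[0]
        pos = matrix.pos[rows]
        X = X_all[rows]
        M = (~np.isnan(X)).astype(float)
        X0 = np.nan_to_num(X)
        X0sq = X0 * X0
        n_chr = len(rows)
        for b0 in range(0, n_chr, block_size):
            b1 = min(b0 + block_size, n_chr)
            lo = int(np.searchsorted(pos, pos[b0] - radius, side="left"))
            hi = int(np.searchsorted(pos, pos[b1 - 1] + radius, side="right"))
            A, Ma, Asq = X0[b0:b1], M[b0:b1], X0sq[b0:b1]
            B, Mb, Bsq = X0[lo:hi], M[lo:hi], X0sq[lo:hi]
            N = Ma @ Mb.T
            Sx = A @ Mb.T
            Sy = Ma @ B.T
            Sxy = A @ B.T
            Sxx = Asq @ Mb.T
            Syy = Ma @ Bsq.T
            cov = N * Sxy - Sx * Sy
            varx = N * Sxx - Sx * Sx
            vary = N * Syy - Sy * Sy
            dist = np.abs(pos[b0:b1, None] - pos[None, lo:hi])
            in_window = dist <= radius
            # exclude self-pairs
            ii = np.arange(b0, b1)[:, None] == np.arange(lo, hi)[None, :]
            valid = in_window & ~ii & (N >= 2) & (varx > 0) & (vary > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(valid, (cov * cov) / (varx * vary), np.nan)
            k = valid.sum(axis=1)
            s = np.nansum(np.where(valid, r2, 0.0), axis=1)
            res = np.full(b1 - b0, np.nan)
            nz = k > 0
            res[nz] = s[nz] / k[nz]
            out[rows[b0:b1]] = res
    return out


# ---------------------------------------------------------------------------
# derived allele frequencies
# ---------------------------------------------------------------------------

def daf(
    matrix: GenotypeMatrix,
    anc_base: np.ndarray,
    anc_prob: np.ndarray,
    prob_threshold: float = 0.6,
    alt_freq: np.ndarray | None = None,
) -> np.ndarray:
    """Derived allele frequency over the panel, polarised by ancestral calls.

    The derived allele is the one differing from the ancestral base.  DAF is
    missing when the ancestral probability is <= ``prob_threshold`` (only
    confident calls, strictly above the threshold, are polarised) or when the
    ancestral base matches neither allele.
    """
    if alt_freq is None:
        alt_freq = panel_alt_freq(matrix)
    anc_base = np.asarray(anc_base, dtype=object)
    anc_prob = np.asarray(anc_prob, dtype=float)
    out = np.full(matrix.n_variants, np.nan)
    confident = anc_prob > prob_threshold
    is_ref = confident & (anc_base == matrix.ref)
    is_alt = confident & (anc_base == matrix.alt)
    out[is_ref] = alt_freq[is_ref]
    out[is_alt] = 1.0 - alt_freq[is_alt]
    return out


def daf_spectrum(dafs: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Proportion of non-missing DAF values per bin.

    Bins are left-closed right-open, except the last which is closed; the
    proportions sum to one.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = np.asarray(dafs, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no non-missing DAF values to bin")
    counts, _ = np.histogram(vals, bins=edges)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# AFD.LD candidate calling
# ---------------------------------------------------------------------------

@dataclass
class CandidateCall:
    """Outcome of the AFD.LD rule: indicator plus the thresholds applied."""

    indicator: np.ndarray  # bool per SNP
    afd_threshold: float
    ld_threshold: float
    afd_percentile: float | None = None
    ld_percentile: float | None = None


def call_afd_ld_candidates(
    afd_col: np.ndarray,
    ld_col: np.ndarray,
    afd_percentile: float = 95.0,
    ld_percentile: float = 95.0,
    fixed_thresholds: tuple[float, float] | None = None,
    min_n: int = 20,
) -> CandidateCall:
    """Flag SNPs whose AFD and windowed LD both exceed high thresholds.

    Thresholds default to empirical percentiles (linear interpolation between
    order statistics) of the genome-wide non-missing distributions; passing
    ``fixed_thresholds=(t_afd, t_ld)`` overrides them.  The comparison is
    strict (>) on both axes; a SNP with a missing value on either axis is
    never a candidate.
    """
    afd_col = np.asarray(afd_col, dtype=float)
    ld_col = np.asarray(ld_col, dtype=float)
    if afd_col.shape != ld_col.shape:
        raise ValueError("AFD and LD columns are not aligned")
    if fixed_thresholds is not None:
        t_afd, t_ld = map(float, fixed_thresholds)
        pa = pl = None
    else:
        a = afd_col[~np.isnan(afd_col)]
        l = ld_col[~np.isnan(ld_col)]
        if len(a) < min_n or len(l) < min_n:
            raise ValueError(
                f"fewer than {min_n} non-missing values; percentile unstable"
            )
        t_afd = float(np.percentile(a, afd_percentile))
        t_ld = float(np.percentile(l, ld_percentile))
        pa, pl = afd_percentile, ld_percentile
    with np.errstate(invalid="ignore"):
        ind = (afd_col > t_afd) & (ld_col > t_ld)
    return CandidateCall(ind, t_afd, t_ld, pa, pl)


# ---------------------------------------------------------------------------
# sliding-window candidate-density scan
# ---------------------------------------------------------------------------

def window_scan(
    chrom: np.ndarray,
    pos: np.ndarray,
    qualifies: np.ndarray,
    window_bp: int = 20_000,
    step_bp: int = 1_000,
) -> pd.DataFrame:
    """Sliding-window ratio of qualifying SNPs over all SNPs.

    Windows of ``window_bp`` advance by ``step_bp`` along each chromosome,
    starting at the first SNP position; the last window is the first one
    whose start exceeds the last SNP.  Empty windows carry a NaN ratio.
    Returns a frame with chrom, start, end, n_total, n_qualifying, ratio.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    qualifies = np.asarray(qualifies, dtype=bool)
    records = []
    for c in pd.unique(chrom):
        rows = np.where(chrom == c)[0]
        p = pos[rows]
        q = qualifies[rows]
        qcum = np.concatenate([[0], np.cumsum(q)])
        first, last = int(p[0]), int(p[-1])
        start = first
        while start <= last:
            end = start + window_bp - 1
            i = int(np.searchsorted(p, start, side="left"))
            j = int(np.searchsorted(p, end, side="right"))
            n_total = j - i
            n_q = int(qcum[j] - qcum[i])
            ratio = n_q / n_total if n_total else np.nan
            records.append((c, start, end, n_total, n_q, ratio))
            start += step_bp
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_total", "n_qualifying", "ratio"]
    )


# ---------------------------------------------------------------------------
# assembled per-SNP table
# ---------------------------------------------------------------------------

def build_variant_table(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    ld_window_bp: int = 20_000,
    neighbor_mode: str = "distance",
    anc_base: np.ndarray | None = None,
    anc_prob: np.ndarray | None = None,
    anc_prob_threshold: float = 0.6,
    afd_percentile: float = 95.0,
    ld_percentile: float = 95.0,
    fixed_thresholds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, CandidateCall]:
    """Assemble the full per-SNP statistics table.

    Computes focal-population frequencies, AFD, windowed mean r-squared over
    the focal pair and over the whole panel, DAF (when ancestral calls are
    given) and the AFD.LD candidate flag.  Returns the table alongside the
    thresholds used for candidate calling.
    """
    popmap.validate_against(matrix)
    f_a = allele_freq(matrix, popmap, popmap.pop_a)
    f_b = allele_freq(matrix, popmap, popmap.pop_b)
    afd_col = afd(f_a, f_b)
    focal_idx = matrix.sample_indices(popmap.focal_samples())
    ld_focal = snp_mean_r2(matrix, focal_idx, ld_window_bp, neighbor_mode)
    ld_panel = snp_mean_r2(matrix, None, ld_window_bp, neighbor_mode)
    table = matrix.variant_frame()
    table["f_a"] = f_a
    table["f_b"] = f_b
    table["afd"] = afd_col
    table["ld_focal"] = ld_focal
    table["ld_panel"] = ld_panel
    if anc_base is not None:
        table["anc_base"] = anc_base
        table["anc_prob"] = anc_prob
        table["daf"] = daf(matrix, anc_base, anc_prob, anc_prob_threshold)
    else:
        table["anc_base"] = "NA"
        table["anc_prob"] = np.nan
        table["daf"] = np.nan
    call = call_afd_ld_candidates(
        afd_col, ld_focal, afd_percentile, ld_percentile, fixed_thresholds
    )
    table["afdld_candidate"] = call.indicator
    return table, call
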