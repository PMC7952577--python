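"""Quantification of Sort-seq bin read counts into dose-response vectors.

Each library variant i is observed as raw read counts R(i,j,k) over six
inducer levels j and eight fluorescence bins k.  The pipeline:

1. normalise reads by the per-(level, bin) cell fractions reported by the
   sorter, N = R x %cells, so read numbers are comparable across bins;
2. apply read-support filters (every bin above 30 reads for a level to be
   used; more than 300 reads in total for a variant to be kept);
3. per retained (variant, level), renormalise the 8-bin histogram, cumulate
   it, and fit a cumulative Gaussian
   0.5 + 0.5*erf((Bin - mu)/(sigma*sqrt(2))) against the bin upper-edge
   fluorescences, keeping levels with fit R^2 above 0.5;
4. normalise mu per variant by its maximum over usable levels, and rescale
   by the per-level mean over negative controls to remove day-to-day
   systematic fluorescence distortions;
5. drop variants whose basal expression (mean over the three lowest inducer
   levels) falls below 15% of the positive-control mean.

All filter inequalities are strict, exactly as worded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

READ_MIN_PER_BIN = 30      # level usable only if every bin is above this
READ_MIN_TOTAL = 300       # variant kept only if total reads exceed this
FIT_R2_MIN = 0.5           # level usable only if fit R^2 exceeds this
BASAL_FRACTION = 0.15      # basal filter vs positive controls
N_LEVELS, N_BINS = 6, 8


@dataclass
class ReadCountTensor:
    """Per-variant 6x8 raw read counts with sorter metadata.

    counts: (n_variants, 6, 8) nonnegative integers.
    cell_fraction: %cells(j,k), the fraction of all sorted cells that fell
    into bin k at level j.  bin_max_fluor: (6, 8) bin upper-edge
    fluorescences, strictly increasing along k.
    """

    variant_ids: list
    counts: np.ndarray
    cell_fraction: np.ndarray
    bin_max_fluor: np.ndarray
    unassigned: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.cell_fraction = np.asarray(self.cell_fraction, dtype=float)
        self.bin_max_fluor = np.asarray(self.bin_max_fluor, dtype=float)
        n = len(self.variant_ids)
        if self.counts.shape != (n, N_LEVELS, N_BINS):
            raise ValueError(f"counts must be (n, {N_LEVELS}, {N_BINS})")
        if self.cell_fraction.shape != (N_LEVELS, N_BINS):
            raise ValueError("cell_fraction must be (6, 8)")
        if self.bin_max_fluor.shape != (N_LEVELS, N_BINS):
            raise ValueError("bin_max_fluor must be (6, 8)")
        if not (np.diff(self.bin_max_fluor, axis=1) > 0).all():
            raise ValueError("bin_max_fluor must be strictly increasing per level")

    # ------------------------------------------------------------------ io
    def to_csv(self, counts_path, cells_path, edges_path):
        long = self.to_frame()
        long.to_csv(counts_path, index=False)
        grid = [(j + 1, k + 1) for j in range(N_LEVELS) for k in range(N_BINS)]
        pd.DataFrame({"level": [j for j, _ in grid], "bin": [k for _, k in grid],
                      "cell_fraction": self.cell_fraction.ravel()}
                     ).to_csv(cells_path, index=False)
        pd.DataFrame({"level": [j for j, _ in grid], "bin": [k for _, k in grid],
                      "max_fluor": self.bin_max_fluor.ravel()}
                     ).to_csv(edges_path, index=False)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.variant_ids, range(1, N_LEVELS + 1), range(1, N_BINS + 1)],
            names=["variant_id", "level", "bin"])
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()

    @classmethod
    def from_csv(cls, counts_path, cells_path, edges_path) -> "ReadCountTensor":
        long = pd.read_csv(counts_path)
        piv = long.pivot_table(index="variant_id", columns=["level", "bin"],
                               values="count", fill_value=0, sort=False)
        ids = list(piv.index)
        counts = piv.to_numpy().reshape(len(ids), N_LEVELS, N_BINS)
        cells = pd.read_csv(cells_path).pivot(index="level", columns="bin",
                                              values="cell_fraction").to_numpy()
        edges = pd.read_csv(edges_path).pivot(index="level", columns="bin",
                                              values="max_fluor").to_numpy()
        return cls(ids, counts, cells, edges)


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def demux_fastq(handle, level_bin_barcodes: dict, variant_barcodes: dict,
                cell_fraction=None, bin_max_fluor=None) -> ReadCountTensor:
    """Exact-match demultiplexing of simulated/real reads into a tensor.

    level_bin_barcodes maps a 5' barcode to a (level, bin) pair (1-based);
    variant_barcodes maps the following variant barcode to a variant id.
    Reads failing either lookup are tallied as unassigned, never guessed.
    """
    def _as_table(table, what):
        if isinstance(table, dict):
            return table
        out = {}
        for barcode, value in table:
            if barcode in out:
                raise ValueError(f"duplicate {what} barcode {barcode!r}")
            out[barcode] = value
        return out

    level_bin_barcodes = _as_table(level_bin_barcodes, "level/bin")
    variant_barcodes = _as_table(variant_barcodes, "variant")
    shared = set(level_bin_barcodes) & set(variant_barcodes)
    if shared and len({len(b) for b in level_bin_barcodes}
                     | {len(b) for b in variant_barcodes}) == 1:
        raise ValueError(f"barcode {shared.pop()!r} appears in both tables")
    lb_len = {len(b) for b in level_bin_barcodes}
    vb_len = {len(b) for b in variant_barcodes}
    if len(lb_len) != 1 or len(vb_len) != 1:
        raise ValueError("barcodes within a table must share one length")
    lb_len, vb_len = lb_len.pop(), vb_len.pop()

    ids = list(dict.fromkeys(variant_barcodes.values()))
    row = {v: i for i, v in enumerate(ids)}
    counts = np.zeros((len(ids), N_LEVELS, N_BINS), dtype=int)
    unassigned = 0
    for lineno, line in enumerate(handle):
        if lineno % 4 != 1:            # FASTQ sequence lines only
            continue
        seq = line.strip()
        lb, vb = seq[:lb_len], seq[lb_len:lb_len + vb_len]
        if lb in level_bin_barcodes and vb in variant_barcodes:
            j, k = level_bin_barcodes[lb]
            counts[row[variant_barcodes[vb]], j - 1, k - 1] += 1
        else:
            unassigned += 1
    if cell_fraction is None:
        cell_fraction = np.full((N_LEVELS, N_BINS), np.nan)
    if bin_max_fluor is None:
        bin_max_fluor = np.tile(np.arange(1.0, N_BINS + 1), (N_LEVELS, 1))
    return ReadCountTensor(ids, counts, cell_fraction, bin_max_fluor,
                           unassigned=unassigned)


# ---------------------------------------------------------------------------
# normalisation and filters
# ---------------------------------------------------------------------------

def normalize_reads(t: ReadCountTensor) -> np.ndarray:
    """N(i,j,k) = R(i,j,k) x %cells(j,k)."""
    if np.isnan(t.cell_fraction).any():
        raise ValueError("cell_fraction contains missing entries")
    return t.counts * t.cell_fraction[None, :, :]


def filter_read_support(t: ReadCountTensor) -> tuple:
    """Strict read-support filters on the RAW counts.

    Returns (variant_keep (n,), level_keep (n, 6)): a level is usable only
    if all eight of its bins are above 30 reads; a variant is kept only if
    its full 6x8 matrix exceeds 300 reads.
    """
    level_keep = (t.counts > READ_MIN_PER_BIN).all(axis=2)
    variant_keep = t.counts.sum(axis=(1, 2)) > READ_MIN_TOTAL
    return variant_keep, level_keep


# ---------------------------------------------------------------------------
# cumulative-Gaussian level fit
# ---------------------------------------------------------------------------

def renormalize_level(nreads: np.ndarray) -> np.ndarray:
    """Scale one level's 8 normalised read values to sum to 1."""
    nreads = np.asarray(nreads, dtype=float)
    total = nreads.sum()
    if total <= 0:
        raise ValueError("cannot renormalize an all-zero level")
    return nreads / total


def cumulate(probs: np.ndarray) -> np.ndarray:
    return np.cumsum(probs)


def _gauss_cdf(x, mu, sigma):
    return 0.5 + 0.5 * erf((x - mu) / (sigma * np.sqrt(2.0)))


def fit_bin_gaussian(nreads: np.ndarray, edges: np.ndarray) -> tuple:
    """Fit a cumulative Gaussian to one level's cumulative read histogram.

    nreads are the 8 cell-fraction-normalised read values, edges the 8 bin
    upper-edge fluorescences.  Returns (mu, sigma, r2) from an unweighted
    least-squares fit at the 8 edge abscissae; mu is initialised at the
    read-weighted mean of the edges and bounded to [min edge/10, max
    edge*10].
    """
    edges = np.asarray(edges, dtype=float)
    probs = renormalize_level(nreads)
    cum = cumulate(probs)
    mu0 = float(np.sum(probs * edges))
    sig0 = float(np.sqrt(np.sum(probs * (edges - mu0) ** 2)))
    lo_mu, hi_mu = edges.min() / 10.0, edges.max() * 10.0
    sig_lo, sig_hi = 1e-9, edges.max() * 10.0
    p0 = [np.clip(mu0, lo_mu, hi_mu), np.clip(sig0, max(sig_lo, 1e-3), sig_hi)]
    try:
        popt, _ = curve_fit(_gauss_cdf, edges, cum, p0=p0,
                            bounds=([lo_mu, sig_lo], [hi_mu, sig_hi]), maxfev=10000)
        mu, sigma = float(popt[0]), float(popt[1])
    except RuntimeError:
        mu, sigma = p0[0], p0[1]
    resid = cum - _gauss_cdf(edges, mu, sigma)
    ss_tot = float(np.sum((cum - cum.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return mu, sigma, r2


# ---------------------------------------------------------------------------
# per-variant pipeline
# ---------------------------------------------------------------------------

def fit_all_levels(t: ReadCountTensor) -> pd.DataFrame:
    """Fit every retained (variant, level); long table with usability flags."""
    nreads = normalize_reads(t)
    variant_keep, level_keep = filter_read_support(t)
    rows = []
    for i, vid in enumerate(t.variant_ids):
        if not variant_keep[i]:
            continue
        for j in range(N_LEVELS):
            if not level_keep[i, j] or nreads[i, j].sum() <= 0:
                continue
            mu, sigma, r2 = fit_bin_gaussian(nreads[i, j], t.bin_max_fluor[j])
            rows.append({"variant_id": vid, "level": j + 1, "mu": mu,
                         "sigma": sigma, "r2": r2, "usable": r2 > FIT_R2_MIN})
    return pd.DataFrame(rows, columns=["variant_id", "level", "mu", "sigma",
                                       "r2", "usable"])


def rescale_dose_response(fits: pd.DataFrame, negative_ids,
                          min_levels: int = 3) -> pd.DataFrame:
    """Per-variant normalisation (mu_norm) and negative-control rescaling
    (mu_tilde) of the fitted means.

    Variants with fewer than ``min_levels`` usable levels are dropped; every
    appearing level must be covered by at least one usable negative control.
    """
    usable = fits[fits["usable"]].copy()
    n_usable = usable.groupby("variant_id")["level"].transform("size")
    usable = usable[n_usable >= min_levels].copy()
    usable["mu_norm"] = usable["mu"] / usable.groupby("variant_id")["mu"].transform("max")

    negative_ids = set(negative_ids)
    negs = usable[usable["variant_id"].isin(negative_ids)]
    mu_neg = negs.groupby("level")["mu_norm"].mean()
    missing = set(usable["level"].unique()) - set(mu_neg.index)
    if missing:
        raise ValueError(f"no usable negative control at level(s) {sorted(missing)}")
    usable["mu_tilde"] = usable["mu_norm"] / usable["level"].map(mu_neg)
    return usable


def basal_expression_filter(dose: pd.DataFrame, positive_ids) -> set:
    """Variants retained by the basal-expression filter.

    A variant is dropped iff the mean of its rescaled fluorescence over the
    three lowest inducer levels is strictly below 15% of the same mean over
    the positive controls.
    """
    low = dose[dose["level"].isin((1, 2, 3))]
    per_variant = low.groupby("variant_id")["mu_tilde"].mean()
    pos = per_variant[per_variant.index.isin(set(positive_ids))]
    if pos.empty:
        raise ValueError("no positive control with usable low-inducer levels")
    cutoff = BASAL_FRACTION * pos.mean()
    keep = set(per_variant[per_variant >= cutoff].index)
    # variants without any usable low level cannot be assessed; keep them
    keep |= set(dose["variant_id"]) - set(per_variant.index)
    return keep


def tilde_matrix(dose: pd.DataFrame) -> pd.DataFrame:
    """Wide (variant x 6 levels) matrix of mu_tilde with NaN for missing."""
    wide = dose.pivot(index="variant_id", columns="level", values="mu_tilde")
    return wide.reindex(columns=range(1, N_LEVELS + 1))


def quantify(t: ReadCountTensor, negative_ids, positive_ids,
             min_levels: int = 3) -> pd.DataFrame:
    """Full tensor -> rescaled dose-response pipeline with all filters."""
    fits = fit_all_levels(t)
    if fits.empty:
        warnings.warn("no (variant, level) passed the read-support filters")
        return fits
    dose = rescale_dose_response(fits, negative_ids, min_levels=min_levels)
    keep = basal_expression_filter(dose, positive_ids)
    return dose[dose["variant_id"].isin(keep)].reset_index(drop=True)
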