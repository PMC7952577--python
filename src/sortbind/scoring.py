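"""Responsiveness scoring: how binder-like is a variant's dose-response?

Each variant's rescaled dose-response is summarised by three features — the
slope and goodness of fit of a linear regression against inducer index, and
the standard deviation over the three highest induction levels.  Positive
and negative control populations are fitted with maximum-likelihood
multivariate Gaussians in that 3-D feature space, and the responsiveness
score is the natural-log ratio of the two densities at the variant's
feature vector.  Scores are averaged over the (up to five) barcodes of a
design.  A non-parametric alternative (the "ANN" score) replaces the
Gaussians by mean squared Euclidean distances to the control dose-response
6-vectors.  The positive-control threshold — the value above which a
variant is called a binder, 3.5 on the study this package models — is the
across-protein average of (mean - std) of the non-zero positive-control
scores.

Conventions: natural logarithm throughout; population (1/N) standard
deviations and covariances, consistent with the maximum-likelihood Gaussian
fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BINDER_THRESHOLD = 3.5
DDG_MIN, RSCORE_MIN = -6.667, 3.5   # calibration-pair screening thresholds


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """(slope, fit R^2, std over the three highest levels)."""

    m: float
    r2: float
    std3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.r2, self.std3])


def extract_features(mu_tilde, min_levels: int = 3) -> FeatureVector:
    """Linear-regression features of one rescaled dose-response vector.

    ``mu_tilde`` is a length-6 vector with NaN at unusable levels; the line
    is fitted over present levels against the inducer index (1..6), and
    std3 is the population standard deviation over the present levels among
    {4, 5, 6}.
    """
    y = np.asarray(mu_tilde, dtype=float)
    levels = np.arange(1, len(y) + 1, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < min_levels:
        raise ValueError(f"fewer than {min_levels} usable levels")
    x, yv = levels[ok], y[ok]
    if np.ptp(yv) == 0:
        m, r2 = 0.0, 0.0
    else:
        res = stats.linregress(x, yv)
        m, r2 = float(res.slope), float(res.rvalue ** 2)
    high = y[3:][np.isfinite(y[3:])]
    if high.size == 0:
        raise ValueError("no usable level among the three highest")
    return FeatureVector(m, r2, float(np.std(high)))


def feature_table(tilde: pd.DataFrame, min_levels: int = 3) -> pd.DataFrame:
    """Features for every row of a wide mu_tilde matrix; rows that cannot be
    featurised (too few levels) are dropped."""
    rows = {}
    for vid, vec in tilde.iterrows():
        try:
            f = extract_features(vec.to_numpy(), min_levels)
        except ValueError:
            continue
        rows[vid] = (f.m, f.r2, f.std3)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["m", "r2", "std3"])


# ---------------------------------------------------------------------------
# control Gaussians and the parametric score
# ---------------------------------------------------------------------------

@dataclass
class ControlModel:
    """Maximum-likelihood Gaussian densities of the control populations."""

    mean_pos: np.ndarray
    cov_pos: np.ndarray
    mean_neg: np.ndarray
    cov_neg: np.ndarray

    def swapped(self) -> "ControlModel":
        return ControlModel(self.mean_neg, self.cov_neg,
                            self.mean_pos, self.cov_pos)


def _ml_gaussian(x: np.ndarray) -> tuple:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("at least 2 controls per class required")
    if len(x) < 4:
        warnings.warn("fewer than 4 controls; covariance may be unstable")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, bias=True)    # 1/N maximum likelihood
    cov = np.atleast_2d(cov)
    eps = 1e-8 * np.trace(cov) / cov.shape[0]
    if np.linalg.eigvalsh(cov).min() <= eps:
        cov = cov + max(eps, 1e-12) * np.eye(cov.shape[0])
    return mean, cov


def fit_control_model(pos_features, neg_features) -> ControlModel:
    mean_p, cov_p = _ml_gaussian(np.asarray(pos_features))
    mean_n, cov_n = _ml_gaussian(np.asarray(neg_features))
    return ControlModel(mean_p, cov_p, mean_n, cov_n)


def r_score(f, model: ControlModel) -> float:
    """Natural-log ratio of positive to negative control density at f."""
    x = f.as_array() if isinstance(f, FeatureVector) else np.asarray(f, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature vector")
    lp = stats.multivariate_normal.logpdf(x, model.mean_pos, model.cov_pos)
    ln = stats.multivariate_normal.logpdf(x, model.mean_neg, model.cov_neg)
    return float(lp - ln)


def aggregate_barcodes(scores: pd.Series | pd.DataFrame,
                       design_of=None) -> pd.DataFrame:
    """Average per-barcode scores into one score per design.

    ``scores`` is indexed by barcoded variant id; ``design_of`` maps it to
    the design id (identity if omitted).  Designs with zero surviving
    barcodes are simply absent.
    """
    s = scores if isinstance(scores, pd.Series) else scores.iloc[:, 0]
    designs = s.index.map(design_of) if design_of is not None else s.index
    grouped = s.groupby(designs)
    return pd.DataFrame({"r_score": grouped.mean(),
                         "n_barcodes_used": grouped.size()})


# ---------------------------------------------------------------------------
# non-parametric (average squared distance) score
# ---------------------------------------------------------------------------

def ann_score(x, pos_vectors, neg_vectors) -> float:
    """log(S_neg / S_pos): mean squared Euclidean 6-D distance to the
    negative vs positive control dose-response vectors.

    A variant coinciding with every member of a class gives an infinite
    sentinel (+inf when glued to the positives, -inf to the negatives).
    """
    x = np.asarray(x, dtype=float)
    pos = np.asarray(pos_vectors, dtype=float)
    neg = np.asarray(neg_vectors, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both control sets must be nonempty")
    s_pos = float(np.mean(np.sum((pos - x) ** 2, axis=1)))
    s_neg = float(np.mean(np.sum((neg - x) ** 2, axis=1)))
    if s_pos == 0.0 and s_neg == 0.0:
        return np.nan
    if s_pos == 0.0:
        return np.inf
    if s_neg == 0.0:
        return -np.inf
    return float(np.log(s_neg / s_pos))


# ---------------------------------------------------------------------------
# binder threshold and energy calibration
# ---------------------------------------------------------------------------

def positive_threshold(score_sets) -> float:
    """Across-protein average of mean - population std of the strictly
    positive positive-control scores."""
    per_protein = []
    for s in score_sets:
        s = np.asarray(s, dtype=float)
        s = s[s > 0]
        if s.size == 0:
            raise ValueError("no non-zero positive-control score in a set")
        per_protein.append(s.mean() - s.std())
    return float(np.mean(per_protein))


def calibrate_ddg(pairs: pd.DataFrame, r_wt: float,
                  direction: str = "score_on_kd") -> tuple:
    """Calibrate the linear score-affinity relation and map scores to
    binding free-energy differences.

    ``pairs`` has columns ``r_score`` and ``ddg_ref`` (reference binding
    free-energy differences, k_B T units).  Pairs are screened at
    ddg_ref > -6.667 and r_score > 3.5; the normalised score ratio
    r_score / r_wt is regressed against exp(ddg_ref) (relative Kd), giving
    intercept a and slope b of score = a + b*Kd.  direction="kd_on_score"
    regresses the other way and inverts.  Returns (a, b, mapper) where
    mapper(score) = ln((score / r_wt - a) / b), NaN (flagged) when the
    argument is nonpositive.
    """
    kept = pairs[(pairs["ddg_ref"] > DDG_MIN) & (pairs["r_score"] > RSCORE_MIN)]
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} calibration pairs survive screening")
    ratio = kept["r_score"].to_numpy() / r_wt
    kd = np.exp(kept["ddg_ref"].to_numpy())
    if direction == "score_on_kd":
        res = stats.linregress(kd, ratio)
        a, b = float(res.intercept), float(res.slope)
    elif direction == "kd_on_score":
        res = stats.linregress(ratio, kd)
        a, b = float(-res.intercept / res.slope), float(1.0 / res.slope)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    def mapper(score):
        arg = (np.asarray(score, dtype=float) / r_wt - a) / b
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(arg > 0, np.log(np.where(arg > 0, arg, 1.0)), np.nan)
        return out if out.ndim else float(out)

    return a, b, mapper


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class ResponsivenessModel:
    """Control-Gaussian responsiveness model over a dose-response table.

    Built from a wide mu_tilde matrix (rows: barcoded variant ids, columns:
    the six inducer levels, NaN for unusable levels) plus the positive and
    negative control id sets; ``fit`` estimates the control densities and
    scores every variant.
    """

    def __init__(self, tilde: pd.DataFrame, positive_ids, negative_ids,
                 design_of=None, min_levels: int = 3):
        self.tilde = tilde
        self.positive_ids = set(positive_ids)
        self.negative_ids = set(negative_ids)
        self.design_of = design_of or (lambda v: v)
        self.min_levels = min_levels

    @classmethod
    def from_tensor(cls, tensor, positive_ids, negative_ids, design_of=None,
                    min_levels: int = 3) -> "ResponsivenessModel":
        """Run the full quantification pipeline on a read-count tensor."""
        from .quantify import quantify, tilde_matrix
        dose = quantify(tensor, negative_ids, positive_ids, min_levels=min_levels)
        return cls(tilde_matrix(dose), positive_ids, negative_ids,
                   design_of=design_of, min_levels=min_levels)

    def fit(self, ann: bool = True) -> "ResponsivenessResults":
        feats = feature_table(self.tilde, self.min_levels)
        pos = feats[feats.index.isin(self.positive_ids)]
        neg = feats[feats.index.isin(self.negative_ids)]
        model = fit_control_model(pos.to_numpy(), neg.to_numpy())
        per_bc = pd.Series(
            [r_score(row, model) for row in feats.to_numpy()],
            index=feats.index, name="r_score")
        controls = self.positive_ids | self.negative_ids
        noncontrol = per_bc[~per_bc.index.isin(controls)]
        table = aggregate_barcodes(noncontrol, self.design_of)

        ann_table = None
        if ann:
            complete = self.tilde.dropna()
            pos_v = complete[complete.index.isin(self.positive_ids)].to_numpy()
            neg_v = complete[complete.index.isin(self.negative_ids)].to_numpy()
            if len(pos_v) and len(neg_v):
                rows = complete[~complete.index.isin(controls)]
                per_bc_ann = pd.Series(
                    [ann_score(x, pos_v, neg_v) for x in rows.to_numpy()],
                    index=rows.index, name="ann")
                g = per_bc_ann.groupby(per_bc_ann.index.map(self.design_of))
                ann_table = g.mean().rename("r_score_ann")
        return ResponsivenessResults(self, model, per_bc, table, ann_table)


@dataclass
class ResponsivenessResults:
    """Fitted control densities and the per-design score table."""

    model: ResponsivenessModel
    control_model: ControlModel
    barcode_scores: pd.Series
    _table: pd.DataFrame
    _ann: pd.Series | None = None
    threshold: float = BINDER_THRESHOLD

    @property
    def scores(self) -> pd.DataFrame:
        """Score table sorted by descending responsiveness."""
        out = self._table.copy()
        if self._ann is not None:
            out = out.join(self._ann, how="left")
        out["binder"] = out["r_score"] > self.threshold
        return out.sort_values("r_score", ascending=False)

    def control_scores(self, which: str) -> np.ndarray:
        ids = (self.model.positive_ids if which == "positive"
               else self.model.negative_ids)
        return self.barcode_scores[self.barcode_scores.index.isin(ids)].to_numpy()

    def summary(self) -> str:
        sc = self.scores
        pos = self.control_scores("positive")
        neg = self.control_scores("negative")
        lines = [
            "Responsiveness model (control-Gaussian log-density ratio)",
            "=" * 57,
            f"designs scored:        {len(sc)}",
            f"positive controls:     {pos.size} (mean score {pos.mean():.2f})"
            if pos.size else "positive controls:     0",
            f"negative controls:     {neg.size} (mean score {neg.mean():.2f})"
            if neg.size else "negative controls:     0",
            f"binder threshold:      {self.threshold}",
            f"binders (> threshold): {int(sc['binder'].sum())}",
            "",
            "top designs:",
            sc.head(5).to_string(),
        ]
        return "\n".join(lines)
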