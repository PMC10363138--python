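"""Rater-agreement statistics for repeated ordinal scorings.

Two coefficients compare scoring rounds or raters on the 0/1/2 point scale:

* Cronbach's α over k repeated columns (intra-rater consistency),

      α = k/(k−1) · (1 − Σ_i σ²_item_i / σ²_total),

  with interpretation bands: excellent > 0.9, good 0.75–0.90,
  moderate 0.50–0.75, poor < 0.5.  The numerically identical two-way mixed
  consistency ICC(3,k) is available behind ``method="icc3k"``.

* Weighted Cohen's κ between two raters with disagreement weights
  w_ij = |i−j|/(c−1) (linear, default) or its square (quadratic):

      κ = 1 − Σ w_ij·o_ij / Σ w_ij·e_ij,

  observed proportions o from the contingency table, expected e from the
  marginal products.  Bands: almost perfect 0.81–1.00, substantial
  0.61–0.80, moderate 0.41–0.60, fair 0.21–0.40, slight 0.01–0.20,
  no agreement ≤ 0.
"""

from __future__ import annotations

import numpy as np

from .errors import AgreementInputError

ICC_BANDS = (
    (0.9, "excellent"),
    (0.75, "good"),
    (0.5, "moderate"),
    (-np.inf, "poor"),
)

KAPPA_BANDS = (
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.01, "slight"),
    (-np.inf, "no agreement"),
)


def icc_band(alpha: float) -> str:
    for cut, name in ICC_BANDS:
        if alpha > cut if name == "excellent" else alpha >= cut:
            return name
    return "poor"


def kappa_band(kappa: float) -> str:
    for cut, name in KAPPA_BANDS:
        if kappa >= cut:
            return name
    return "no agreement"


def icc_cronbach(table, method: str = "alpha"):
    """Cronbach's α of a (specimens × raters/rounds) table.

    Returns ``(alpha, band)``.  Identical columns give α = 1 by convention;
    zero total variance with *unequal* columns is undefined and raises.
    ``method="icc3k"`` computes the two-way mixed consistency ICC(3,k)
    instead (equal to α for complete data).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise AgreementInputError("need at least 2 specimens and 2 columns")
    if np.isnan(x).any():
        raise AgreementInputError("missing cells are not supported")
    n, k = x.shape
    if np.all(x == x[:, :1]):
        return 1.0, icc_band(1.0)
    total = x.sum(axis=1)
    var_total = total.var(ddof=1)
    if var_total <= 0:
        raise AgreementInputError(
            "total variance is zero but columns differ; alpha undefined"
        )
    if method == "alpha":
        alpha = k / (k - 1) * (1.0 - x.var(axis=0, ddof=1).sum() / var_total)
    elif method == "icc3k":
        # two-way ANOVA mean squares: rows (specimens) and residual
        grand = x.mean()
        row_means = x.mean(axis=1)
        col_means = x.mean(axis=0)
        ms_rows = k * ((row_means - grand) ** 2).sum() / (n - 1)
        ss_cols = n * ((col_means - grand) ** 2).sum()
        ss_tot = ((x - grand) ** 2).sum()
        ss_err = ss_tot - k * ((row_means - grand) ** 2).sum() - ss_cols
        ms_err = ss_err / ((n - 1) * (k - 1))
        alpha = (ms_rows - ms_err) / ms_rows
    else:
        raise AgreementInputError(f"unknown method {method!r}")
    alpha = float(alpha)
    return alpha, icc_band(alpha)


def weighted_kappa(r1, r2, weights: str = "linear", categories=None):
    """Weighted Cohen's κ between two ordinal rating vectors.

    ``categories`` declares the ordinal scale (default 0, 1, 2); categories
    never used by either rater still shape the weight matrix.  Returns
    ``(kappa, band)``.
    """
    a = np.asarray(r1)
    b = np.asarray(r2)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementInputError("rating vectors must be 1-D and equal length")
    if len(a) == 0:
        raise AgreementInputError("empty ratings")
    cats = np.asarray(categories if categories is not None else [0, 1, 2])
    c = len(cats)
    if c < 2:
        raise AgreementInputError("need at least 2 categories")
    lut = {v: i for i, v in enumerate(cats.tolist())}
    try:
        ia = np.array([lut[v] for v in a.tolist()])
        ib = np.array([lut[v] for v in b.tolist()])
    except KeyError as exc:
        raise AgreementInputError(f"rating outside declared scale: {exc}") from exc
    if len(np.unique(np.concatenate([ia, ib]))) < 2:
        raise AgreementInputError(
            "both raters used a single category; kappa undefined"
        )
    n = len(ia)
    obs = np.zeros((c, c))
    np.add.at(obs, (ia, ib), 1.0)
    obs /= n
    pa = obs.sum(axis=1)
    pb = obs.sum(axis=0)
    exp = np.outer(pa, pb)
    idx = np.arange(c)
    w = np.abs(idx[:, None] - idx[None, :]) / (c - 1)
    if weights == "quadratic":
        w = w**2
    elif weights != "linear":
        raise AgreementInputError(f"unknown weighting {weights!r}")
    denom = (w * exp).sum()
    if denom <= 0:
        raise AgreementInputError("chance disagreement is zero; kappa undefined")
    kappa = float(1.0 - (w * obs).sum() / denom)
    return kappa, kappa_band(kappa)
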