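"""Second-order response-surface fitting and ANOVA diagnostics.

The response surface is the full quadratic polynomial in coded factors

    y = b0 + sum_i bi xi + sum_i bii xi^2 + sum_{i<j} bij xi xj

fitted by QR least squares. The diagnostics mirror the standard
design-of-experiments ANOVA report: per-term Type III sums of squares
and F tests, the lack-of-fit / pure-error decomposition from replicated
runs, the R-squared family (plain, adjusted, prediction via PRESS),
Gaussian-likelihood AICc and BIC, the coefficient of variation and the
adequate-precision signal-to-noise ratio.

All coefficients are reported in coded units; ``predict`` accepts
natural-unit points and codes them through the design's factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignMatrix, FactorSpec, code_point

__all__ = [
    "QuadraticModel",
    "AnovaReport",
    "term_names",
    "model_matrix",
    "fit_quadratic",
    "predict",
    "anova",
    "press_and_predicted_r2",
    "information_criteria",
    "adequacy_stats",
]

RANK_TOL = 1e-10  # relative rank-detection tolerance for the QR factor


def term_names(k: int) -> list[str]:
    """Term labels for the full quadratic model: 1 + 2k + k(k-1)/2 of them."""
    names = ["Intercept"]
    names += [f"X{i + 1}" for i in range(k)]
    names += [f"X{i + 1}^2" for i in range(k)]
    names += [f"X{i + 1}X{j + 1}" for i in range(k) for j in range(i + 1, k)]
    return names


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Columns [1, x_i, x_i^2, x_i x_j (i<j)] for coded points (rows)."""
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = x.shape
    cols = [np.ones(n)]
    cols += [x[:, i] for i in range(k)]
    cols += [x[:, i] ** 2 for i in range(k)]
    cols += [x[:, i] * x[:, j] for i in range(k) for j in range(i + 1, k)]
    return np.column_stack(cols)


class SingularDesignError(np.linalg.LinAlgError):
    """Model matrix is rank-deficient: the design cannot support the model."""


@dataclass
class QuadraticModel:
    """A fitted full second-order polynomial in coded units."""

    response: str
    factors: tuple[FactorSpec, ...]
    coefficients: np.ndarray  # ordered as term_names(k)
    residual_ss: float
    residual_df: int
    n: int

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def p(self) -> int:
        return len(self.coefficients)

    @property
    def terms(self) -> list[str]:
        return term_names(self.k)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": dict(zip(self.terms, map(float, self.coefficients))),
            "residual_ss": self.residual_ss,
            "residual_df": self.residual_df,
            "n": self.n,
        }


def _qr_solve(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    if diag.min() < RANK_TOL * diag.max():
        raise SingularDesignError("rank-deficient model matrix")
    return np.linalg.solve(R, Q.T @ y)


def fit_quadratic(design: DesignMatrix, y: np.ndarray, response: str = "y") -> QuadraticModel:
    """Least-squares fit of the full quadratic to one response column."""
    y = np.asarray(y, dtype=float)
    A = model_matrix(design.coded)
    n, p = A.shape
    if n <= p:
        raise ValueError(f"need more runs ({n}) than coefficients ({p})")
    beta = _qr_solve(A, y)
    resid = y - A @ beta
    return QuadraticModel(
        response=response,
        factors=design.factors,
        coefficients=beta,
        residual_ss=float(resid @ resid),
        residual_df=n - p,
        n=n,
    )


def predict(model: QuadraticModel, point, coded: bool = False) -> float | np.ndarray:
    """Evaluate the polynomial at one point or a batch of points.

    Natural-unit points (default) are coded through the model's factors
    first; pass ``coded=True`` for points already in coded units.
    """
    pt = np.asarray(point, dtype=float)
    single = pt.ndim == 1
    pt = np.atleast_2d(pt)
    if pt.shape[1] != model.k:
        raise ValueError(f"point dimension {pt.shape[1]} != k={model.k}")
    if not coded:
        pt = code_point(pt, model.factors)
    out = model_matrix(pt) @ model.coefficients
    return float(out[0]) if single else out


@dataclass
class TermRow:
    term: str
    coefficient: float
    ss: float
    df: int
    ms: float
    f: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class AnovaReport:
    """The full ANOVA battery for one fitted quadratic response model."""

    response: str
    terms: list[TermRow]
    model_ss: float
    model_df: int
    model_ms: float
    model_f: float
    model_p: float
    residual_ss: float
    residual_df: int
    lack_of_fit_ss: float | None
    lack_of_fit_df: int | None
    lack_of_fit_f: float | None
    lack_of_fit_p: float | None
    pure_error_ss: float | None
    pure_error_df: int | None
    total_ss: float
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    aicc: float
    bic: float
    cv_percent: float
    adequate_precision: float
    has_lack_of_fit: bool = field(default=True)

    def term(self, name: str) -> TermRow:
        for row in self.terms:
            if row.term == name:
                return row
        raise KeyError(name)

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "terms": [
                {
                    "term": t.term,
                    "coefficient": t.coefficient,
                    "ss": t.ss,
                    "df": t.df,
                    "ms": t.ms,
                    "f": t.f,
                    "p": t.p,
                    "significant": t.significant,
                }
                for t in self.terms
            ],
        }
        for key in (
            "model_ss model_df model_ms model_f model_p residual_ss residual_df "
            "lack_of_fit_ss lack_of_fit_df lack_of_fit_f lack_of_fit_p "
            "pure_error_ss pure_error_df total_ss r2 adj_r2 pred_r2 press "
            "aicc bic cv_percent adequate_precision has_lack_of_fit"
        ).split():
            d[key] = getattr(self, key)
        return d


def press_and_predicted_r2(
    model: QuadraticModel, design: DesignMatrix, y: np.ndarray
) -> tuple[float, float]:
    """Leave-one-out PRESS from hat-matrix leverages, and prediction R².

    PRESS = sum_i (e_i / (1 - h_ii))^2 with h_ii the leverage of run i;
    algebraically identical to refitting with each run deleted.
    """
    y = np.asarray(y, dtype=float)
    A = model_matrix(design.coded)
    Q, R = np.linalg.qr(A)
    h = np.sum(Q**2, axis=1)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("degenerate design: a run has leverage 1 (no LOO prediction)")
    resid = y - A @ model.coefficients
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return press, 1.0 - press / sst


def information_criteria(model: QuadraticModel, n: int | None = None, p: int | None = None) -> tuple[float, float]:
    """Small-sample AIC (AICc) and BIC in the Gaussian least-squares form.

    Includes the n*ln(2*pi) + n likelihood constants, so values are
    comparable with standard DOE software output:

        AICc = n ln(2 pi SSE/n) + n + 2p + 2p(p+1)/(n-p-1)
        BIC  = n ln(2 pi SSE/n) + n + p ln n
    """
    n = model.n if n is None else n
    p = model.p if p is None else p
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} <= p+1={p + 1}")
    sse = model.residual_ss
    base = n * np.log(2 * np.pi * sse / n) + n
    aicc = base + 2 * p + 2 * p * (p + 1) / (n - p - 1)
    bic = base + p * np.log(n)
    return float(aicc), float(bic)


def adequacy_stats(
    model: QuadraticModel, design: DesignMatrix, y: np.ndarray
) -> tuple[float, float]:
    """Coefficient of variation (%) and the adequate-precision ratio.

    CV = 100 sqrt(residual MS) / mean(y). Adequate precision is the
    spread of fitted values over the design runs divided by the average
    prediction standard deviation, sqrt(p * residual MS / n); ratios
    above 4 indicate a usable signal-to-noise level.
    """
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if np.isclose(ybar, 0.0):
        raise ValueError("CV undefined: mean response is zero")
    ms_res = model.residual_ss / model.residual_df
    cv = 100.0 * np.sqrt(ms_res) / ybar
    yhat = model_matrix(design.coded) @ model.coefficients
    adeq = (yhat.max() - yhat.min()) / np.sqrt(model.p * ms_res / model.n)
    return float(cv), float(adeq)


def anova(model: QuadraticModel, design: DesignMatrix, y: np.ndarray) -> AnovaReport:
    """Assemble the complete ANOVA report for a fitted quadratic.

    Per-term sums of squares are Type III (partial): SS_j = b_j^2 /
    [(A'A)^-1]_jj, each term adjusted for all others. On a CCD the
    linear and interaction columns are mutually orthogonal, so for them
    this equals b_j^2 * sum(x_j^2); the pure quadratic columns are
    correlated with each other and only the partial form matches
    conventional DOE software reports.

    Pure-error SS pools squared within-group deviations over replicated
    design points; lack-of-fit SS is the remainder of the residual SS.
    """
    y = np.asarray(y, dtype=float)
    A = model_matrix(design.coded)
    n, p = A.shape
    C = np.linalg.inv(A.T @ A)
    beta = model.coefficients
    resid = y - A @ beta
    sse = float(resid @ resid)
    df_res = n - p
    ms_res = sse / df_res
    sst = float(np.sum((y - y.mean()) ** 2))
    ss_model = sst - sse
    df_model = p - 1
    ms_model = ss_model / df_model
    f_model = ms_model / ms_res
    p_model = float(stats.f.sf(f_model, df_model, df_res))

    rows = []
    names = model.terms
    for j in range(1, p):  # the intercept carries no ANOVA row
        ssj = float(beta[j] ** 2 / C[j, j])
        fj = ssj / ms_res
        rows.append(
            TermRow(
                term=names[j],
                coefficient=float(beta[j]),
                ss=ssj,
                df=1,
                ms=ssj,
                f=fj,
                p=float(stats.f.sf(fj, 1, df_res)),
            )
        )

    # lack of fit / pure error from replicate groups
    ss_pe = 0.0
    df_pe = 0
    for idx in design.replicate_groups():
        if len(idx) > 1:
            ss_pe += float(np.sum((y[idx] - y[idx].mean()) ** 2))
            df_pe += len(idx) - 1
    if df_pe >= 1 and df_res > df_pe:
        ss_lof = sse - ss_pe
        df_lof = df_res - df_pe
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        has_lof = True
    else:
        ss_lof = df_lof = f_lof = p_lof = None
        ss_pe = df_pe = None
        has_lof = False

    press, pred_r2 = press_and_predicted_r2(model, design, y)
    aicc, bic = information_criteria(model)
    cv, adeq = adequacy_stats(model, design, y)

    return AnovaReport(
        response=model.response,
        terms=rows,
        model_ss=ss_model,
        model_df=df_model,
        model_ms=ms_model,
        model_f=f_model,
        model_p=p_model,
        residual_ss=sse,
        residual_df=df_res,
        lack_of_fit_ss=ss_lof,
        lack_of_fit_df=df_lof,
        lack_of_fit_f=f_lof,
        lack_of_fit_p=p_lof,
        pure_error_ss=ss_pe,
        pure_error_df=df_pe,
        total_ss=sst,
        r2=1.0 - sse / sst,
        adj_r2=1.0 - (sse / df_res) / (sst / (n - 1)),
        pred_r2=pred_r2,
        press=press,
        aicc=aicc,
        bic=bic,
        cv_percent=cv,
        adequate_precision=adeq,
        has_lack_of_fit=has_lof,
    )
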