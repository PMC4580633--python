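"""Binomial-logit feeding-prediction models with AICc selection.

The modelling surface follows the Model / Results convention: a
:class:`FeedingModel` is built from a covariate table and a
:class:`ModelSpec`, and :meth:`FeedingModel.fit` returns a
:class:`FeedingResults` carrying maximum-likelihood estimates, their
covariance, the small-sample information criterion

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1),

and a ``summary()`` table.  Estimation is iteratively reweighted least
squares through :mod:`statsmodels`; coefficients are reported on the raw
(non-standardized) covariate scale.

Term language
-------------
A model spec is an ordered list of term strings over covariate names:

``"X"``            main effect;
``"log(X)"``       natural-log transform (positivity is checked);
``"X^2"``          quadratic in the raw covariate (requires ``X`` or
                   ``log(X)`` present);
``"A:B"``          product interaction of two already-present terms;
``"SUM"``          season dummy (indicator ``SEAS == "SUM"``).

The reproduced candidate set consists of the 2^4 on/off combinations of four
covariate groups — spatio-temporal (SpTemp), activity (Acvty),
ground-truthing error (GrndTru) and season (Seas) — with the two cross-group
interactions ``ACCX:CENTER`` and ``ACCXYDIFF:log(POSCOUNT)`` included only
when both parent groups are present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "FeedingModel",
    "FeedingResults",
    "SeparationError",
    "aicc",
    "akaike_weights",
    "build_design_matrix",
    "component_candidate_set",
    "select_models",
    "complete_cases",
    "TOP_MODEL_SPEC",
    "GROUPS",
]

log = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Raised when the likelihood diverges (complete/quasi separation)."""


# ---------------------------------------------------------------------------
# Terms and specs
# ---------------------------------------------------------------------------

def _base_column(expr: str, df: pd.DataFrame) -> np.ndarray:
    """Evaluate a non-interaction term expression to a column."""
    if expr == "SUM":
        return (df["SEAS"].astype(str) == "SUM").to_numpy(dtype=float)
    if expr.startswith("log(") and expr.endswith(")"):
        name = expr[4:-1]
        v = df[name].to_numpy(dtype=float)
        if (v <= 0).any():
            bad = np.nonzero(v <= 0)[0][:5].tolist()
            raise ValueError(f"log({name}): non-positive values at rows {bad}")
        return np.log(v)
    if expr.endswith("^2"):
        name = expr[:-2]
        v = df[name].to_numpy(dtype=float)
        return v * v
    return df[expr].to_numpy(dtype=float)


def _covariates_of(expr: str) -> set[str]:
    if expr == "SUM":
        return {"SEAS"}
    if ":" in expr:
        a, b = expr.split(":", 1)
        return _covariates_of(a) | _covariates_of(b)
    if expr.startswith("log(") and expr.endswith(")"):
        return {expr[4:-1]}
    if expr.endswith("^2"):
        return {expr[:-2]}
    return {expr}


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of model terms (the intercept is always included)."""

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        present = set(self.terms)
        for t in self.terms:
            if t.endswith("^2") and ":" not in t:
                parent = t[:-2]
                if parent not in present and f"log({parent})" not in present:
                    raise ValueError(
                        f"{self.name}: quadratic {t!r} requires its main effect"
                    )
            if ":" in t:
                a, b = t.split(":", 1)
                for p in (a, b):
                    if p not in present:
                        raise ValueError(
                            f"{self.name}: interaction {t!r} requires parent {p!r}"
                        )

    @property
    def k(self) -> int:
        return len(self.terms) + 1  # + intercept

    def covariates(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= _covariates_of(t)
        return out


def build_design_matrix(
    df: pd.DataFrame, spec: ModelSpec, response: str | None = "FEEDING"
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Design matrix (with intercept), column names and response vector.

    Rows must be complete for every covariate the spec references (use
    :func:`complete_cases` first); missing values raise.
    """
    for cov in sorted(spec.covariates()):
        if cov not in df.columns:
            raise ValueError(f"missing covariate {cov!r}")
        if cov != "SEAS" and df[cov].isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    cache: dict[str, np.ndarray] = {}

    def col(expr: str) -> np.ndarray:
        if expr not in cache:
            if ":" in expr:
                a, b = expr.split(":", 1)
                cache[expr] = col(a) * col(b)
            else:
                cache[expr] = _base_column(expr, df)
        return cache[expr]

    for t in spec.terms:
        cols.append(col(t))
        names.append(t)
    X = np.column_stack(cols)
    y = None
    if response is not None and response in df.columns:
        y = df[response].to_numpy(dtype=float)
    return X, names, y


def complete_cases(df: pd.DataFrame, specs: Iterable[ModelSpec]) -> pd.DataFrame:
    """Listwise-drop rows missing any covariate used by any spec.

    All models in a comparison set are fitted to the same observations so
    their AICc values are comparable.
    """
    needed: set[str] = set()
    for s in specs:
        needed |= s.covariates()
    needed &= set(df.columns)
    mask = df[sorted(needed)].notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        log.info("complete_cases: dropped %d incomplete rows", dropped)
    return df[mask]


# ---------------------------------------------------------------------------
# Candidate set
# ---------------------------------------------------------------------------

GROUPS: dict[str, tuple[str, ...]] = {
    "SpTemp": ("log(POSCOUNT)", "NIGHTPROP", "log(POSCOUNT):NIGHTPROP",
               "CENTER", "CENTER^2"),
    "Acvty": ("ACCX", "ACCX^2", "ACCXYDIFF"),
    "GrndTru": ("SEARCH_LAG", "FIELDPROP", "FIELDPROP^2"),
    "Seas": ("SUM",),
}
_CROSS = ("ACCX:CENTER", "ACCXYDIFF:log(POSCOUNT)")

TOP_MODEL_SPEC = ModelSpec(
    "SpTemp + Acvty + GrndTru + Seas",
    GROUPS["SpTemp"] + GROUPS["Acvty"] + _CROSS + GROUPS["GrndTru"] + GROUPS["Seas"],
)


def component_candidate_set() -> list[ModelSpec]:
    """The 16 on/off combinations of the four covariate groups.

    The two cross-group interactions appear only when both their parent
    groups (SpTemp and Acvty) are on.  The all-off combination is the
    intercept-only null model.
    """
    order = ["SpTemp", "Acvty", "GrndTru", "Seas"]
    specs = []
    for mask in range(16):
        on = [g for i, g in enumerate(order) if mask & (1 << i)]
        terms: list[str] = []
        for g in order:
            if g in on:
                terms.extend(GROUPS[g])
                if g == "Acvty" and "SpTemp" in on:
                    terms.extend(_CROSS)
        name = " + ".join(on) if on else "Null"
        specs.append(ModelSpec(name, tuple(terms)))
    return specs


def named_spec(name: str) -> ModelSpec:
    """Resolve a spec by name: ``top``/``full``, ``null``, or a ``+``-joined
    combination of the component groups (e.g. ``"SpTemp + Acvty"``)."""
    if name.lower() in ("top", "full"):
        return TOP_MODEL_SPEC
    if name.lower() == "null":
        return ModelSpec("Null", ())
    parts = [p.strip() for p in name.split("+")]
    unknown = [p for p in parts if p not in GROUPS]
    if unknown:
        raise ValueError(f"unknown component(s) {unknown}; known: {list(GROUPS)}")
    terms: list[str] = []
    for g in GROUPS:
        if g in parts:
            terms.extend(GROUPS[g])
            if g == "Acvty" and "SpTemp" in parts:
                terms.extend(_CROSS)
    return ModelSpec(" + ".join(p for p in GROUPS if p in parts), tuple(terms))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights from a set of AICc values (invariant to shifts)."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


class FeedingModel:
    """Binomial-logit model of feeding presence at GPS clusters.

    Parameters
    ----------
    endog
        Binary response vector (1 = feeding remains present).
    exog
        Design matrix including the intercept column.
    names
        Column names aligned with ``exog``.
    spec
        The :class:`ModelSpec` the matrix was built from, if any.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        names: list[str],
        spec: ModelSpec | None = None,
    ) -> None:
        endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if endog.ndim != 1 or exog.shape[0] != endog.shape[0]:
            raise ValueError("endog/exog shapes do not conform")
        if not np.isin(endog, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if exog.shape[0] <= exog.shape[1]:
            raise ValueError(
                f"need n > k, got n={exog.shape[0]}, k={exog.shape[1]}"
            )
        rank = np.linalg.matrix_rank(exog)
        if rank < exog.shape[1]:
            bad = _collinear_columns(exog, names)
            raise ValueError(f"design matrix is rank deficient; check {bad}")
        self.endog = endog
        self.exog = exog
        self.names = list(names)
        self.spec = spec

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: ModelSpec, response: str = "FEEDING"
    ) -> "FeedingModel":
        data = complete_cases(df, [spec])
        X, names, y = build_design_matrix(data, spec, response)
        if y is None:
            raise ValueError(f"response column {response!r} not found")
        return cls(y, X, names, spec)

    def fit(self, maxiter: int = 100, tol: float = 1e-10) -> "FeedingResults":
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = glm.fit(maxiter=maxiter, tol=tol, scale=1.0)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            raise SeparationError(
                "perfect separation detected: the likelihood has no finite "
                "maximum"
            )
        beta = np.asarray(res.params, dtype=float)

        # scale-aware divergence guard for separated data
        scale = self.exog.std(axis=0)
        scale[scale == 0] = 1.0
        if np.any(np.abs(beta) * scale > 50.0):
            j = int(np.argmax(np.abs(beta) * scale))
            raise SeparationError(
                f"coefficient for {self.names[j]!r} diverged "
                "(complete or quasi-complete separation)"
            )
        converged = bool(getattr(res, "converged", True))
        if not converged:
            raise RuntimeError(f"IRLS did not converge in {maxiter} iterations")
        k = self.exog.shape[1]
        n = self.exog.shape[0]
        return FeedingResults(
            model=self,
            params=pd.Series(beta, index=self.names),
            cov_params=pd.DataFrame(
                np.asarray(res.cov_params()), index=self.names, columns=self.names
            ),
            llf=float(res.llf),
            k=k,
            n=n,
            aicc=aicc(float(res.llf), k, n),
            converged=converged,
        )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.nonzero(diag < tol)[0]]


@dataclass
class FeedingResults:
    """Maximum-likelihood fit of a :class:`FeedingModel`."""

    model: FeedingModel
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    k: int
    n: int
    aicc: float
    converged: bool

    @property
    def spec(self) -> ModelSpec | None:
        return self.model.spec

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    def linpred(self, df: pd.DataFrame) -> np.ndarray:
        if self.spec is None:
            raise ValueError("results carry no spec; cannot rebuild the design")
        X, names, _ = build_design_matrix(df, self.spec, response=None)
        assert names == list(self.params.index)
        return X @ self.params.to_numpy()

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Fitted feeding probabilities for covariate rows."""
        from scipy.special import expit

        return expit(self.linpred(df))

    def fittedvalues(self) -> np.ndarray:
        from scipy.special import expit

        return expit(self.model.exog @ self.params.to_numpy())

    def summary(self) -> pd.DataFrame:
        """Coefficient table with Wald standard errors and 95% intervals."""
        se = self.bse
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": se,
                "z": self.params / se,
                "ci_low": self.params - 1.96 * se,
                "ci_high": self.params + 1.96 * se,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        name = self.spec.name if self.spec else "<custom>"
        return (
            f"<FeedingResults {name!r}: k={self.k} n={self.n} "
            f"logLik={self.llf:.1f} AICc={self.aicc:.1f}>"
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "spec": {"name": self.spec.name, "terms": list(self.spec.terms)}
            if self.spec
            else None,
            "names": list(self.params.index),
            "beta": self.params.to_numpy().tolist(),
            "vcov": self.cov_params.to_numpy().tolist(),
            "logLik": self.llf,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "FeedingResults":
        with open(path) as fh:
            payload = json.load(fh)
        spec = (
            ModelSpec(payload["spec"]["name"], tuple(payload["spec"]["terms"]))
            if payload["spec"]
            else None
        )
        names = payload["names"]
        dummy_model = FeedingModel.__new__(FeedingModel)
        dummy_model.spec = spec
        dummy_model.names = names
        dummy_model.endog = None
        dummy_model.exog = None
        return cls(
            model=dummy_model,
            params=pd.Series(payload["beta"], index=names),
            cov_params=pd.DataFrame(payload["vcov"], index=names, columns=names),
            llf=payload["logLik"],
            k=payload["k"],
            n=payload["n"],
            aicc=payload["aicc"],
            converged=True,
        )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_models(
    specs: Sequence[ModelSpec],
    df: pd.DataFrame,
    response: str = "FEEDING",
    on_error: str = "raise",
) -> tuple[pd.DataFrame, dict[str, FeedingResults]]:
    """Fit every spec on a common observation set and rank by AICc.

    Returns the selection table (sorted ascending by AICc, with ΔAICc and
    Akaike weights) and the fitted results keyed by model name.
    ``on_error="drop"`` excludes models whose likelihood has no finite
    maximum (separation) instead of raising; their absence is logged.
    """
    if not specs:
        raise ValueError("no model specs given")
    if on_error not in ("raise", "drop"):
        raise ValueError("on_error must be 'raise' or 'drop'")
    data = complete_cases(df, specs)
    results: dict[str, FeedingResults] = {}
    rows = []
    for spec in specs:
        try:
            res = FeedingModel.from_dataframe(data, spec, response).fit()
        except SeparationError as exc:
            if on_error == "drop":
                log.warning("model %r dropped from selection: %s", spec.name, exc)
                continue
            raise RuntimeError(f"model {spec.name!r} failed to fit: {exc}") from exc
        except Exception as exc:
            raise RuntimeError(f"model {spec.name!r} failed to fit: {exc}") from exc
        results[spec.name] = res
        rows.append(
            {"model": spec.name, "k": res.k, "logLik": res.llf, "AICc": res.aicc}
        )
    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    table["dAICc"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["AICc"].to_numpy())
    return table, results
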