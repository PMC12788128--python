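"""Maximum-entropy species distribution model, fitted from scratch.

The model is the classic presence/background Gibbs formulation: over a set
of background cells the species' distribution is

    raw(z) = exp(lambda . f(z)) / Z

where f(z) are bounded feature transforms of the environmental variables
(linear, quadratic, product, hinge, threshold) and Z normalizes over the
background.  Coefficients maximize the regularized training gain

    gain = mean_presence(lambda . f) - ln E_background[exp(lambda . f)]
           - sum_j beta_j |lambda_j|

by cyclic coordinate-wise proximal (soft-thresholded Newton) descent with
backtracking, so the gain is non-decreasing across updates.  The per-feature
penalty is beta_j = RM * base(class, m) * sd_j(presence) / sqrt(m) with the
conventional per-class base tables.  The "logistic" output rescales raw with
c = exp(H) (H the entropy of the raw distribution) so that a completely
uninformative model scores exactly 0.5 everywhere.

Model selection tunes the regularization multiplier (RM, default 0.5..4 by
0.5) against a menu of feature-class combinations (L, H, LQ, LQH, LQPH,
LQPHT) and picks the candidate with delta AICc = 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .grids import EnvStack, Raster, SuitabilityRaster

logger = logging.getLogger("nichekit")

FEATURE_MENU = ("L", "H", "LQ", "LQH", "LQPH", "LQPHT")
DEFAULT_RM_GRID = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_HINGE_KNOTS = 20
MIN_BACKGROUND = 100
MAX_BACKGROUND = 10_000

#: AUC performance bands: (0.5, 0.7] poor, (0.7, 0.9] moderate, > 0.9 high.
AUC_BANDS = ((0.7, "poor performance"), (0.9, "moderate performance"), (np.inf, "high performance"))

# Per-class base penalties interpolated on presence sample size m
# (reference defaults; the table is configurable through fit_maxent).
DEFAULT_BETA_TABLE: dict[str, list[tuple[float, float]]] = {
    "L": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "Q": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "P": [(10, 1.0), (30, 0.2), (100, 0.05)],
    "H": [(0, 0.5)],
    "T": [(10, 2.0), (100, 1.0)],
}

_SD_FLOOR = 1e-3  # numerical floor on presence feature sd inside beta


def base_penalty(kind: str, m: int, table=None) -> float:
    """Piecewise-linear interpolation of the per-class base penalty in m."""
    pts = (table or DEFAULT_BETA_TABLE)[kind]
    ms = [p[0] for p in pts]
    vs = [p[1] for p in pts]
    return float(np.interp(m, ms, vs))


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureColumn:
    kind: str                     # one of L Q P H T
    vars: tuple[str, ...]
    knot: float | None = None
    direction: str | None = None  # 'fwd' / 'rev' for hinge

    @property
    def name(self) -> str:
        tag = "*".join(self.vars)
        if self.kind in ("L", "Q", "P"):
            return f"{self.kind}({tag})"
        return f"{self.kind}({tag},{self.direction or ''}{self.knot:.3f})"


@dataclass
class FeatureSpec:
    """Feature-class menu plus background-derived min/max normalizers."""

    classes: str
    variables: list[str]
    hinge_knots: int = DEFAULT_HINGE_KNOTS
    normalizers: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.classes) - set("LQPHT")
        if bad:
            raise ValueError(f"unknown feature classes {sorted(bad)}")
        if ("Q" in self.classes or "P" in self.classes) and "L" not in self.classes:
            raise ValueError("Q/P features require L in the class set")
        if ("H" in self.classes or "T" in self.classes) and self.hinge_knots < 2:
            raise ValueError("hinge/threshold features need >= 2 knots")

    @classmethod
    def from_background(
        cls,
        classes: str,
        background: pd.DataFrame,
        hinge_knots: int = DEFAULT_HINGE_KNOTS,
    ) -> "FeatureSpec":
        normalizers = {
            v: (float(background[v].min()), float(background[v].max()))
            for v in background.columns
        }
        return cls(classes, list(background.columns), hinge_knots, normalizers)

    # -- column layout ----------------------------------------------------
    def _constant_vars(self) -> set[str]:
        return {v for v, (lo, hi) in self.normalizers.items() if hi <= lo}

    def columns(self) -> list[FeatureColumn]:
        const = self._constant_vars()
        if const:
            logger.warning("constant variable(s) %s: Q/P/H/T features dropped", sorted(const))
        cols: list[FeatureColumn] = []
        k = self.hinge_knots
        fwd_knots = np.linspace(0.0, 1.0, k, endpoint=False)
        rev_knots = fwd_knots + 1.0 / k
        t_knots = np.linspace(0.0, 1.0, k + 2)[1:-1]
        for kind in "LQPHT":
            if kind not in self.classes:
                continue
            if kind == "L":
                cols += [FeatureColumn("L", (v,)) for v in self.variables]
            elif kind == "Q":
                cols += [FeatureColumn("Q", (v,)) for v in self.variables if v not in const]
            elif kind == "P":
                cols += [
                    FeatureColumn("P", (a, b))
                    for a, b in itertools.combinations(self.variables, 2)
                    if a not in const and b not in const
                ]
            elif kind == "H":
                for v in self.variables:
                    if v in const:
                        continue
                    cols += [FeatureColumn("H", (v,), float(t), "fwd") for t in fwd_knots]
                    cols += [FeatureColumn("H", (v,), float(t), "rev") for t in rev_knots]
            elif kind == "T":
                for v in self.variables:
                    if v in const:
                        continue
                    cols += [FeatureColumn("T", (v,), float(t)) for t in t_knots]
        return cols

    def scaled(self, frame: pd.DataFrame) -> dict[str, np.ndarray]:
        """Min-max scale each variable to [0, 1] (clipped outside background range)."""
        out = {}
        for v in self.variables:
            lo, hi = self.normalizers[v]
            x = frame[v].to_numpy(float)
            out[v] = np.clip((x - lo) / (hi - lo), 0.0, 1.0) if hi > lo else np.zeros(len(x))
        return out

    def build(self, frame: pd.DataFrame) -> np.ndarray:
        """Feature matrix for rows of raw variable values."""
        missing = [v for v in self.variables if v not in frame.columns]
        if missing:
            raise KeyError(f"variables missing from input: {missing}")
        L = self.scaled(frame)
        cols = self.columns()
        X = np.empty((len(frame), len(cols)))
        for j, c in enumerate(cols):
            if c.kind == "L":
                X[:, j] = L[c.vars[0]]
            elif c.kind == "Q":
                X[:, j] = L[c.vars[0]] ** 2
            elif c.kind == "P":
                X[:, j] = L[c.vars[0]] * L[c.vars[1]]
            elif c.kind == "H":
                x = L[c.vars[0]]
                t = c.knot
                if c.direction == "fwd":
                    X[:, j] = np.clip((x - t) / (1.0 - t), 0.0, 1.0) if t < 1 else 0.0
                else:
                    X[:, j] = np.clip((t - x) / t, 0.0, 1.0) if t > 0 else 0.0
            else:  # T
                X[:, j] = (x := L[c.vars[0]]) >= c.knot
        return X


def build_features(spec: FeatureSpec, frame: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`FeatureSpec.build`."""
    return spec.build(frame)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    feature_spec: FeatureSpec
    columns: list[FeatureColumn]
    lambdas: np.ndarray
    logZ: float            # log sum over background of exp(lambda.f)
    n_background: int
    entropy_H: float       # entropy (nats) of the raw distribution over background
    rm: float
    training_gain: float
    gain_trace: list[float] = field(default_factory=list)
    var_credits: dict[str, float] = field(default_factory=dict)
    presence_var_means: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def k(self) -> int:
        """Number of nonzero coefficients."""
        return int(np.count_nonzero(self.lambdas))

    # -- scoring ----------------------------------------------------------
    def scores(self, frame: pd.DataFrame) -> np.ndarray:
        return self.feature_spec.build(frame) @ self.lambdas

    def raw(self, frame: pd.DataFrame) -> np.ndarray:
        """Raw (Gibbs) output; sums to 1 when evaluated over the background."""
        return np.exp(self.scores(frame) - self.logZ)

    def logistic(self, frame: pd.DataFrame) -> np.ndarray:
        c_raw = np.exp(self.entropy_H + self.scores(frame) - self.logZ)
        return c_raw / (1.0 + c_raw)


def fit_maxent(
    presence: np.ndarray,
    background: np.ndarray,
    columns: list[FeatureColumn],
    feature_spec: FeatureSpec | None = None,
    rm: float = 1.0,
    beta_table: dict | None = None,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    presence_var_means: dict[str, float] | None = None,
) -> MaxentModel:
    """Fit the L1-regularized Gibbs model by coordinate proximal descent.

    ``presence`` and ``background`` are feature matrices over the same
    columns.  Convergence is declared when a full sweep improves the gain by
    less than *tol*; the gain is non-decreasing across coordinate updates by
    construction (each Newton step is backtracked until it does not hurt).
    """
    presence = np.asarray(presence, float)
    background = np.asarray(background, float)
    if presence.ndim != 2 or background.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if presence.shape[0] < 1:
        raise ValueError("need at least one presence row")
    if background.shape[0] < MIN_BACKGROUND:
        raise ValueError(f"need at least {MIN_BACKGROUND} background rows")
    if not (np.isfinite(presence).all() and np.isfinite(background).all()):
        raise ValueError("non-finite feature values")
    if rm <= 0:
        raise ValueError("rm must be > 0")

    m, p = presence.shape
    n_b = background.shape[0]
    mean_p = presence.mean(axis=0)
    sd_p = presence.std(axis=0)
    beta = np.array(
        [
            rm * base_penalty(c.kind, m, beta_table) * max(sd_p[j], _SD_FLOOR) / np.sqrt(m)
            for j, c in enumerate(columns)
        ]
    )

    lam = np.zeros(p)
    s_b = np.zeros(n_b)
    log_nb = np.log(n_b)

    def total_gain(lam_vec, s_vec):
        return float(lam_vec @ mean_p - (logsumexp(s_vec) - log_nb) - beta @ np.abs(lam_vec))

    gain = 0.0
    gain_trace = [gain]
    credits: dict[str, float] = {}
    converged = False
    lsz = float(logsumexp(s_b))
    for sweep in range(max_sweeps):
        sweep_start = gain
        for j in range(p):
            w = np.exp(s_b - lsz)
            xj = background[:, j]
            Ef = float(w @ xj)
            Ef2 = float(w @ (xj * xj))
            g = mean_p[j] - Ef
            h = max(Ef2 - Ef * Ef, 1e-10)
            z = lam[j] + g / h
            thr = beta[j] / h
            target = np.sign(z) * max(abs(z) - thr, 0.0)
            d = target - lam[j]
            if d == 0.0:
                continue
            accepted = False
            for _ in range(40):
                lam_j_new = lam[j] + d
                s_new = s_b + d * xj
                lsz_new = float(logsumexp(s_new))
                new_gain = (
                    gain
                    - lam[j] * mean_p[j] + lam_j_new * mean_p[j]
                    + (lsz - lsz_new)
                    - beta[j] * (abs(lam_j_new) - abs(lam[j]))
                )
                if new_gain >= gain - 1e-12:
                    accepted = True
                    break
                d *= 0.5
            if not accepted:
                continue
            inc = max(new_gain - gain, 0.0)
            share = inc / len(columns[j].vars)
            for v in columns[j].vars:
                credits[v] = credits.get(v, 0.0) + share
            lam[j] = lam_j_new
            s_b = s_new
            lsz = lsz_new
            gain = new_gain
        gain_trace.append(gain)
        if gain - sweep_start < tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_maxent: not converged after %d sweeps (last gain %.6f)", max_sweeps, gain)

    logZ = float(logsumexp(s_b))
    w = np.exp(s_b - logZ)
    entropy = float(-(w * np.where(w > 0, np.log(w), 0.0)).sum())
    return MaxentModel(
        feature_spec=feature_spec,
        columns=columns,
        lambdas=lam,
        logZ=logZ,
        n_background=n_b,
        entropy_H=entropy,
        rm=rm,
        training_gain=gain,
        gain_trace=gain_trace,
        var_credits=credits,
        presence_var_means=presence_var_means or {},
        converged=converged,
    )


def fit_from_tables(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    classes: str = "LQ",
    rm: float = 1.0,
    hinge_knots: int = DEFAULT_HINGE_KNOTS,
    **kwargs,
) -> MaxentModel:
    """Convenience wrapper: derive normalizers from background and fit."""
    spec = FeatureSpec.from_background(classes, background, hinge_knots)
    Xp = spec.build(presence)
    Xb = spec.build(background)
    means = {v: float(presence[v].mean()) for v in presence.columns}
    return fit_maxent(
        Xp, Xb, spec.columns(), feature_spec=spec, rm=rm,
        presence_var_means=means, **kwargs,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model: MaxentModel, stack: EnvStack, output: str = "logistic") -> SuitabilityRaster:
    """Project the model over a stack; output 'raw' or 'logistic'."""
    if output not in ("raw", "logistic"):
        raise ValueError("output must be 'raw' or 'logistic'")
    spec_vars = model.feature_spec.variables
    missing = [v for v in spec_vars if v not in stack.names]
    if missing:
        raise KeyError(f"variable(s) missing from stack: {missing}")
    valid = stack.valid_mask()
    frame = pd.DataFrame({v: stack[v].values[valid] for v in spec_vars})
    vals = model.raw(frame) if output == "raw" else model.logistic(frame)
    grid = np.full(valid.shape, stack.spec.nodata)
    grid[valid] = vals
    return Raster(stack.spec, grid, ~valid)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc(scores_presence, scores_background) -> tuple[float, str]:
    """Rank-based (Mann-Whitney) AUC with ties counted 0.5, plus its band label."""
    from scipy.stats import rankdata

    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.concatenate([sp, sb])
    if np.ptp(pooled) == 0:
        logger.warning("auc: constant scores; AUC = 0.5")
        value = 0.5
    else:
        ranks = rankdata(pooled)
        value = float((ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2) / (sp.size * sb.size))
    for cut, label in AUC_BANDS:
        if value <= cut:
            return value, label
    return value, AUC_BANDS[-1][1]


def aicc(model: MaxentModel, occ_features: np.ndarray, all_features: np.ndarray):
    """Small-sample-corrected AIC of the raw distribution over all cells.

    Returns (k, lnL, AICc, valid).  The likelihood renormalizes the Gibbs
    density over *all_features*; k counts nonzero coefficients.  The
    candidate is invalid when k >= n - 1 (correction denominator <= 0).
    """
    n = occ_features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 occurrences")
    k = model.k
    s_occ = occ_features @ model.lambdas
    s_all = all_features @ model.lambdas
    lnL = float(s_occ.sum() - n * logsumexp(s_all))
    if n - k - 1 <= 0:
        return k, lnL, np.nan, False
    value = 2 * k - 2 * lnL + (2 * k * (k + 1)) / (n - k - 1)
    return k, lnL, float(value), True


# ---------------------------------------------------------------------------
# RM x FC tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    table: pd.DataFrame
    selected: dict
    model: MaxentModel


def tune(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    rm_grid=DEFAULT_RM_GRID,
    fc_menu=FEATURE_MENU,
    hinge_knots: int = DEFAULT_HINGE_KNOTS,
    test_fraction: float = 0.25,
    seed: int = 0,
    max_sweeps: int = 200,
) -> TuneResult:
    """Evaluate every RM x FC candidate and select delta AICc = 0.

    The default grids (8 RMs x 6 FCs) give 48 candidates.  Ties on AICc are
    broken by higher test AUC, then fewer parameters, then lexicographic FC.
    """
    rm_grid = list(rm_grid)
    fc_menu = list(fc_menu)
    if not rm_grid or not fc_menu:
        raise ValueError("rm_grid and fc_menu must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(presence)
    idx = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    rows = []
    fitted = {}
    for fc in fc_menu:
        spec = FeatureSpec.from_background(fc, background, hinge_knots)
        cols = spec.columns()
        Xb = spec.build(background)
        Xp_all = spec.build(presence)
        Xp_train, Xp_test = Xp_all[train_idx], Xp_all[test_idx]
        for rm in rm_grid:
            model = fit_maxent(
                Xp_train, Xb, cols, feature_spec=spec, rm=rm, max_sweeps=max_sweeps,
                presence_var_means={v: float(presence[v].iloc[train_idx].mean()) for v in presence.columns},
            )
            k, lnL, value, valid = aicc(model, Xp_all, Xb)
            s_b = Xb @ model.lambdas
            train_auc, _ = auc(Xp_train @ model.lambdas, s_b)
            if len(test_idx) > 0:
                test_auc, _ = auc(Xp_test @ model.lambdas, s_b)
            else:
                test_auc = np.nan
            rows.append(
                dict(fc=fc, rm=float(rm), k=k, lnL=lnL, aicc=value,
                     train_auc=train_auc, test_auc=test_auc, valid=valid)
            )
            fitted[(fc, float(rm))] = model
    table = pd.DataFrame(rows)
    ok = table[table["valid"]]
    if ok.empty:
        raise RuntimeError("all tuning candidates invalid (k >= n - 1)")
    best_aicc = ok["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best_aicc
    cand = table[table["valid"] & (table["delta_aicc"] <= 1e-9)].copy()
    cand["_ta"] = cand["test_auc"].fillna(-np.inf)
    cand = cand.sort_values(by=["_ta", "k", "fc"], ascending=[False, True, True])
    sel = cand.iloc[0]
    selected = dict(fc=sel["fc"], rm=float(sel["rm"]), k=int(sel["k"]),
                    aicc=float(sel["aicc"]), test_auc=float(sel["test_auc"]),
                    train_auc=float(sel["train_auc"]))
    return TuneResult(table.drop(columns=[c for c in table.columns if c.startswith("_")]),
                      selected, fitted[(sel["fc"], float(sel["rm"]))])


# ---------------------------------------------------------------------------
# Variable importance and response curves
# ---------------------------------------------------------------------------

def jackknife_gains(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    classes: str = "LQ",
    rm: float = 1.0,
    hinge_knots: int = DEFAULT_HINGE_KNOTS,
    max_sweeps: int = 200,
) -> pd.DataFrame:
    """Training gain with only / without each variable at fixed RM/FC."""
    variables = list(presence.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")

    def _gain(vars_subset):
        model = fit_from_tables(
            presence[vars_subset], background[vars_subset], classes=classes,
            rm=rm, hinge_knots=hinge_knots, max_sweeps=max_sweeps,
        )
        return model.training_gain

    gain_full = _gain(variables)
    rows = []
    for v in variables:
        rows.append(
            dict(
                variable=v,
                gain_only=_gain([v]),
                gain_without=_gain([u for u in variables if u != v]),
                gain_full=gain_full,
            )
        )
    return pd.DataFrame(rows)


def response_curves(
    model: MaxentModel,
    variable: str,
    mode: str = "marginal",
    presence: pd.DataFrame | None = None,
    background: pd.DataFrame | None = None,
    n_samples: int = 100,
) -> pd.DataFrame:
    """Logistic suitability along one variable's background range.

    marginal: other variables held at their presence means; only: a model
    refit on that variable alone (requires presence and background tables).
    """
    if variable not in model.feature_spec.variables:
        raise KeyError(f"{variable!r} not in model")
    lo, hi = model.feature_spec.normalizers[variable]
    xs = np.linspace(lo, hi, n_samples)
    if mode == "marginal":
        data = {}
        for v in model.feature_spec.variables:
            if v == variable:
                data[v] = xs
            else:
                data[v] = np.full(n_samples, model.presence_var_means.get(v, (lo + hi) / 2))
        ys = model.logistic(pd.DataFrame(data))
    elif mode == "only":
        if presence is None or background is None:
            raise ValueError("'only' mode needs presence and background tables")
        sub = fit_from_tables(
            presence[[variable]], background[[variable]],
            classes=model.feature_spec.classes, rm=model.rm,
            hinge_knots=model.feature_spec.hinge_knots,
        )
        ys = sub.logistic(pd.DataFrame({variable: xs}))
    else:
        raise ValueError("mode must be 'marginal' or 'only'")
    return pd.DataFrame({variable: xs, "suitability": ys})


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Per-variable share (%) of the accumulated coordinate gain increments.

    Each accepted coordinate update's gain increment is credited to the
    feature's underlying variable(s) (product features split 50/50); credits
    are clipped at zero and normalized to sum to 100.
    """
    credits = {v: max(c, 0.0) for v, c in model.var_credits.items()}
    for v in model.feature_spec.variables:
        credits.setdefault(v, 0.0)
    total = sum(credits.values())
    if total <= 0:
        logger.warning("percent_contribution: zero total credit")
        return {v: 0.0 for v in credits}
    return {v: 100.0 * c / total for v, c in credits.items()}


# ---------------------------------------------------------------------------
# Replicate schemes
# ---------------------------------------------------------------------------

def replicate_scheme(n: int, level: str = "species", n_replicates: int = 10):
    """Data-partitioning scheme by sample size.

    Genus-level models always use subsampling with a 25% test split.
    Species-level: n >= 50 -> 30% test; 20 <= n < 50 -> 40% test; n < 15 ->
    bootstrap with no held-out test.  The 15 <= n < 20 range is not covered
    by the published scheme and is mapped to the 40% split with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if level == "genus":
        return "subsample", 0.25, n_replicates
    if n >= 50:
        return "subsample", 0.30, n_replicates
    if n >= 20:
        return "subsample", 0.40, n_replicates
    if n >= 15:
        logger.warning("replicate_scheme: %d samples falls outside the published rules; using 40%% test", n)
        return "subsample", 0.40, n_replicates
    return "bootstrap", 0.0, n_replicates


def average_replicates(rasters: list[SuitabilityRaster]) -> SuitabilityRaster:
    """Cell-wise arithmetic mean of replicate logistic outputs."""
    from .grids import require_aligned

    require_aligned(*rasters)
    mask = rasters[0].mask.copy()
    for r in rasters[1:]:
        mask |= r.mask
    stackvals = np.mean([r.values for r in rasters], axis=0)
    stackvals[mask] = rasters[0].spec.nodata
    return Raster(rasters[0].spec, stackvals, mask)
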