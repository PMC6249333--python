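"""Multivariate Ratio Analysis (MRA) core.

Linear measurements of commensurate body parts carry a dominant joint
size signal.  Working on natural logarithms, each specimen's *isosize*
is the mean of its log measurements (the log geometric mean) and its
*shape* vector is the per-variable deviation from that mean.  Ratios of
raw measurements become differences of shape components, so an analysis
of shape vectors is an analysis of all body ratios at once:

* ``shape_pca`` — PCA of the shape vectors; its loadings live in the
  subspace orthogonal to the equal-weights (isometric size) direction.
* ``pca_ratio_spectrum`` — orders a PC's loadings on a line; variable
  pairs far apart define the ratios that best approximate that PC, with
  optional bootstrap intervals on the loadings.
* ``allometry_diagnostics`` — regresses a shape PC on isosize per group
  to check whether groups lie on a common allometric axis, i.e. whether
  their shape difference could be a mere size effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from morphokey.measurement_io import MEASUREMENT_CODES, MeasurementTable

#: Variables excluded from the default shape analysis because of their
#: higher measurement error.
DEFAULT_EXCLUDED: tuple[str, ...] = ("eye.l", "hea.l", "tmp.l")

#: Default 28-variable selection: the full vocabulary minus the
#: high-error variables above.
DEFAULT_SHAPE_VARIABLES: tuple[str, ...] = tuple(
    c for c in MEASUREMENT_CODES if c not in DEFAULT_EXCLUDED
)


@dataclass
class LogShapeData:
    """Log-scale size/shape decomposition of a measurement table.

    ``isosize[i]`` is the mean natural log measurement of specimen i;
    ``shape.loc[i]`` is its vector of log deviations from that mean, so
    each row of ``shape`` sums to zero.  Multiplying a specimen's raw
    measurements by ``c`` adds ``ln c`` to its isosize and leaves its
    shape untouched.
    """

    isosize: pd.Series
    shape: pd.DataFrame
    group: pd.Series
    dropped: tuple[str, ...] = ()

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.shape.columns)

    @property
    def n_specimens(self) -> int:
        return len(self.shape)


@dataclass
class ShapePcaResult:
    """Principal components of shape space.

    ``loadings`` is a (k, p) array of orthonormal row vectors, each
    summing to zero (orthogonal to the isometric direction); eigenvalues
    are descending; ``variance_fraction`` is each eigenvalue as a percent
    of total shape variance and sums to 100 over the retained PCs.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    variables: tuple[str, ...]
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class RatioSpectrum:
    """One-dimensional ordering of a shape PC's loadings.

    Variables at the two extremes define the single ratio that best
    approximates the PC; variables clustered near the centre contribute
    little.  Optional bootstrap intervals (resampling specimens with
    replacement, sign-aligned to the point estimate) quantify the
    stability of each loading.
    """

    pc: int
    order: tuple[str, ...]
    loadings: pd.Series
    intervals: pd.DataFrame | None = None
    n_boot: int = 0
    seed: int | None = None

    @property
    def extreme_pair(self) -> tuple[str, str]:
        """(highest-loading variable, lowest-loading variable)."""
        return self.order[-1], self.order[0]


@dataclass
class GroupAllometry:
    group: str
    slope: float | None
    intercept: float | None
    slope_se: float | None
    n: int


@dataclass
class AllometryDiagnostics:
    """Per-group regressions of a shape PC score on isosize.

    ``offset`` is the fitted between-group difference in score at the
    pooled mean isosize under a common-slope (ANCOVA) model;
    ``common_axis`` is False when that offset exceeds ``offset_se_factor``
    standard errors, i.e. when the groups do not lie on one shared
    size–shape trend.
    """

    pc: int
    fits: tuple[GroupAllometry, ...]
    offset: float
    offset_se: float | None
    common_axis: bool
    offset_se_factor: float = 2.0


def to_log_shape(
    table: MeasurementTable, variables: Sequence[str] | None = None
) -> LogShapeData:
    """Decompose a measurement table into isosize and shape.

    ``variables`` defaults to the 28-variable selection
    :data:`DEFAULT_SHAPE_VARIABLES`.  Specimens missing any selected
    value are dropped listwise and reported in ``dropped``.
    """
    if variables is None:
        variables = [v for v in DEFAULT_SHAPE_VARIABLES if v in table.variables]
    variables = list(variables)
    missing = [v for v in variables if v not in table.variables]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    if len(variables) < 2:
        raise ValueError("at least 2 variables are required for shape analysis")
    sub = table.data[variables]
    complete = sub.notna().all(axis=1)
    dropped = tuple(sub.index[~complete])
    sub = sub.loc[complete]
    if len(sub) < 3:
        raise ValueError("at least 3 complete specimens are required")
    logs = np.log(sub)
    isosize = logs.mean(axis=1)
    shape = logs.sub(isosize, axis=0)
    return LogShapeData(
        isosize=isosize.rename("isosize"),
        shape=shape,
        group=table.species.loc[sub.index].copy(),
        dropped=dropped,
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    out = loadings.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


def shape_pca(data: LogShapeData) -> ShapePcaResult:
    """PCA of the covariance of shape vectors.

    The shape matrix is centred across specimens and decomposed by SVD.
    Because every shape vector sums to zero, all loadings are orthogonal
    to the equal-weights direction and at most ``p - 1`` eigenvalues are
    nonzero.  Variance fractions are percentages of total shape variance
    (the trace of the shape covariance).  Signs follow a deterministic
    convention: each loading's largest-magnitude component is positive.
    """
    X = data.shape.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 specimens and 2 variables")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total <= 0:
        k = min(n - 1, p - 1)
        return ShapePcaResult(
            loadings=np.zeros((k, p)),
            eigenvalues=np.zeros(k),
            variance_fraction=np.zeros(k),
            scores=pd.DataFrame(
                np.zeros((n, k)),
                index=data.shape.index,
                columns=[f"PC{i + 1}" for i in range(k)],
            ),
            variables=data.variables,
            degenerate=True,
        )
    # drop numerically-zero trailing components; the rank of centred shape
    # data is at most min(n-1, p-1) (one dof to centring, one to the
    # isometric null direction)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    keep = s > tol
    keep[min(n - 1, p - 1):] = False
    eig = eig[keep]
    loadings = _fix_signs(vt[keep])
    scores = Xc @ loadings.T
    return ShapePcaResult(
        loadings=loadings,
        eigenvalues=eig,
        variance_fraction=100.0 * eig / eig.sum(),
        scores=pd.DataFrame(
            scores,
            index=data.shape.index,
            columns=[f"PC{i + 1}" for i in range(loadings.shape[0])],
        ),
        variables=data.variables,
    )


def pca_ratio_spectrum(
    result: ShapePcaResult,
    pc: int = 0,
    data: LogShapeData | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> RatioSpectrum:
    """Ratio spectrum of one shape PC.

    Orders variables by their loading on PC ``pc`` (0-based).  With
    ``n_boot > 0`` (requires ``data``), specimens are resampled with
    replacement, the shape PCA is recomputed, each replicate's loading
    vector is sign-aligned to the point estimate by dot product, and
    percentile 95% intervals per variable are reported.  Intervals are
    widened, when necessary, to contain the point estimate.
    """
    if not 0 <= pc < result.n_components:
        raise IndexError(f"pc {pc} out of range (0..{result.n_components - 1})")
    if n_boot < 0:
        raise ValueError("bootstrap replicate count must be >= 0")
    point = pd.Series(result.loadings[pc], index=list(result.variables))
    order = tuple(point.sort_values().index)
    intervals = None
    if n_boot > 0:
        if data is None:
            raise ValueError("bootstrap requires the original LogShapeData")
        rng = np.random.default_rng(seed)
        n = data.n_specimens
        ref = point.to_numpy()
        reps = np.empty((n_boot, len(ref)))
        idx = np.arange(n)
        for b in range(n_boot):
            take = rng.choice(idx, size=n, replace=True)
            boot = LogShapeData(
                isosize=data.isosize.iloc[take].reset_index(drop=True),
                shape=data.shape.iloc[take].reset_index(drop=True),
                group=data.group.iloc[take].reset_index(drop=True),
            )
            bres = shape_pca(boot)
            k = min(pc, bres.n_components - 1)
            vec = bres.loadings[k]
            if vec @ ref < 0:
                vec = -vec
            reps[b] = vec
        low = np.minimum(np.percentile(reps, 2.5, axis=0), ref)
        high = np.maximum(np.percentile(reps, 97.5, axis=0), ref)
        intervals = pd.DataFrame(
            {"low": low, "high": high}, index=list(result.variables)
        )
    return RatioSpectrum(
        pc=pc,
        order=order,
        loadings=point,
        intervals=intervals,
        n_boot=n_boot,
        seed=seed,
    )


def allometry_diagnostics(
    result: ShapePcaResult,
    data: LogShapeData,
    pc: int = 0,
    offset_se_factor: float = 2.0,
) -> AllometryDiagnostics:
    """Check whether groups share a common allometric axis.

    Fits score-on-isosize OLS lines per group, then a pooled
    common-slope model with a group indicator.  The indicator
    coefficient is the between-group score offset at equal size; when it
    exceeds ``offset_se_factor`` standard errors the groups are judged
    not to lie on a common axis, so their shape difference is not a size
    artefact.  Defined for one or two groups.
    """
    if not 0 <= pc < result.n_components:
        raise IndexError(f"pc {pc} out of range")
    score = result.scores.iloc[:, pc]
    iso = data.isosize.loc[score.index]
    groups = data.group.loc[score.index]
    labels = sorted(groups.unique())
    fits = []
    for g in labels:
        mask = groups == g
        x = iso[mask].to_numpy()
        y = score[mask].to_numpy()
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
        if np.ptp(x) == 0:
            fits.append(GroupAllometry(g, None, None, None, len(x)))
            continue
        X = sm.add_constant(x)
        ols = sm.OLS(y, X).fit()
        se = float(ols.bse[1]) if len(x) > 2 else None
        fits.append(
            GroupAllometry(
                g,
                slope=float(ols.params[1]),
                intercept=float(ols.params[0]),
                slope_se=se,
                n=len(x),
            )
        )
    if len(labels) == 1:
        return AllometryDiagnostics(
            pc=pc,
            fits=tuple(fits),
            offset=0.0,
            offset_se=None,
            common_axis=True,
            offset_se_factor=offset_se_factor,
        )
    if len(labels) != 2:
        raise ValueError("allometry diagnostics are defined for 1 or 2 groups")
    indicator = (groups == labels[1]).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(iso)), iso.to_numpy(), indicator])
    ols = sm.OLS(score.to_numpy(), X).fit()
    offset = float(ols.params[2])
    offset_se = float(ols.bse[2])
    common = abs(offset) <= offset_se_factor * offset_se
    return AllometryDiagnostics(
        pc=pc,
        fits=tuple(fits),
        offset=offset,
        offset_se=offset_se,
        common_axis=bool(common),
        offset_se_factor=offset_se_factor,
    )


def scores_to_frame(result: ShapePcaResult, data: LogShapeData) -> pd.DataFrame:
    """Plotting coordinates: specimen, group, isosize, PC scores."""
    out = pd.DataFrame(
        {
            "specimen_id": result.scores.index,
            "group": data.group.loc[result.scores.index].to_numpy(),
            "isosize": data.isosize.loc[result.scores.index].to_numpy(),
        }
    )
    for col in result.scores.columns:
        out[col] = result.scores[col].to_numpy()
    return out


def spectrum_to_frame(spectrum: RatioSpectrum) -> pd.DataFrame:
    """Spectrum coordinates (pc, variable, loading, low, high), sorted by loading."""
    rows = []
    for var in spectrum.order:
        row = {
            "pc": spectrum.pc + 1,
            "variable": var,
            "loading": float(spectrum.loadings[var]),
        }
        if spectrum.intervals is not None:
            row["low"] = float(spectrum.intervals.loc[var, "low"])
            row["high"] = float(spectrum.intervals.loc[var, "high"])
        rows.append(row)
    return pd.DataFrame(rows)
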