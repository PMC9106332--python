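"""Population-level metrics: signal clarity, decoding, subspace geometry.

Signal clarity of an output channel is the absolute difference of its
absolute Pearson correlations with the two sources; normalised by the sum
of the two correlations it lies in [0, 1], with 1 a clean separation and
~0.5 the reference level of the raw mixed stimuli.  Linear decoders probe
for an invariant population subspace (a single decoder generalising to
novel contexts), and total-least-squares plane fits in the space spanned
by the two readout axes and the residual first principal component
measure how feedback reorients the population representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import PolynomialFeatures

from .exceptions import InvalidParameterError, UndefinedMetricError
from .task import MixingMatrix

__all__ = [
    "ClarityReport",
    "DecodingReport",
    "SubspaceReport",
    "correlation",
    "signal_clarity",
    "clarity_by_context",
    "per_neuron_clarity",
    "clarity_readout_correlation",
    "decode_sources",
    "decode_context",
    "context_mean_activity",
    "inverse_context_targets",
    "subspace_coordinates",
    "fit_plane",
    "plane_angle",
    "angle_vs_context_distance",
]


@dataclass
class ClarityReport:
    """Clarity values keyed by context (rows) and channel (columns)."""

    values: pd.DataFrame
    stage: str = "y"
    normalized: bool = True

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values.to_numpy()))


@dataclass
class DecodingReport:
    """Cross-context decoding performance."""

    target: str
    decoder: str
    r2: pd.DataFrame
    train_contexts: list = field(default_factory=list)
    test_contexts: list = field(default_factory=list)
    n_train_samples: int = 0

    @property
    def mean_r2(self) -> float:
        return float(self.r2["r2"].mean())


@dataclass
class SubspaceReport:
    """Folded plane angles versus context distances for context pairs."""

    pairs: pd.DataFrame
    pearson_r: float = np.nan
    p_value: float = np.nan


# ---------------------------------------------------------------------------
# clarity


def correlation(u, v) -> float:
    """Pearson correlation coefficient over time."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise InvalidParameterError("u and v must have equal length >= 2")
    if u.std() == 0 or v.std() == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    return float(np.corrcoef(u, v)[0, 1])


def signal_clarity(outputs, sources, normalized: bool = True) -> np.ndarray:
    """Per-channel signal clarity.

    For two sources, channel j scores ||r_1j| - |r_2j||, divided by
    |r_1j| + |r_2j| when ``normalized``.  For more than two sources the
    best-vs-second-best generalisation of the same contrast is used.
    ``outputs``/``sources`` are (T, n_channels) / (T, n_s) arrays.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float).T).T
    sources = np.atleast_2d(np.asarray(sources, dtype=float).T).T
    n_out = outputs.shape[1]
    n_s = sources.shape[1]
    clarity = np.empty(n_out)
    for j in range(n_out):
        r = np.array([abs(correlation(sources[:, i], outputs[:, j])) for i in range(n_s)])
        top = np.sort(r)[::-1][:2]
        if top.sum() == 0:
            raise UndefinedMetricError("clarity undefined: both correlations are zero")
        clarity[j] = (top[0] - top[1]) / (top.sum() if normalized else 1.0)
    return clarity


def clarity_by_context(outputs, sources, context_index, normalized: bool = True,
                       stage: str = "y") -> ClarityReport:
    """Channel-wise clarity per context (clarity measured over the whole
    duration of each context)."""
    context_index = np.asarray(context_index)
    rows = {}
    for ctx in np.unique(context_index):
        sel = context_index == ctx
        rows[int(ctx)] = signal_clarity(outputs[sel], sources[sel], normalized)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "context"
    return ClarityReport(values=df, stage=stage, normalized=normalized)


def per_neuron_clarity(activity, sources, context_index, normalized: bool = True):
    """Clarity of every neuron's trace in every context; silent neurons are
    flagged NaN and excluded from averages."""
    activity = np.asarray(activity, dtype=float)
    context_index = np.asarray(context_index)
    contexts = np.unique(context_index)
    out = np.full((activity.shape[1], len(contexts)), np.nan)
    for k, ctx in enumerate(contexts):
        sel = context_index == ctx
        for n in range(activity.shape[1]):
            trace = activity[sel, n]
            if trace.std() == 0:
                continue  # silent neuron: undefined, excluded
            try:
                out[n, k] = signal_clarity(trace[:, None], sources[sel], normalized)[0]
            except UndefinedMetricError:
                continue
    return out


def clarity_readout_correlation(mean_clarity, readout_weights):
    """Pearson r (and two-sided p) between per-neuron mean clarity and the
    magnitude of the neuron's readout weight (Euclidean norm across output
    channels)."""
    mean_clarity = np.asarray(mean_clarity, dtype=float)
    W = np.asarray(readout_weights, dtype=float)
    magnitude = np.linalg.norm(W, axis=0) if W.ndim == 2 else np.abs(W)
    valid = np.isfinite(mean_clarity)
    r, p = stats.pearsonr(mean_clarity[valid], magnitude[valid])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# decoding


def decode_sources(
    activity_by_context,
    sources_by_context,
    n_train_ctx: int = 10,
    n_test_ctx: int = 10,
    rng: np.random.Generator | None = None,
) -> DecodingReport:
    """Fit one linear decoder of the sources on ``n_train_ctx`` contexts and
    score R^2 on held-out contexts.

    ``activity_by_context`` and ``sources_by_context`` are arrays of shape
    (n_contexts, n_t, dim).  At the defaults (10 contexts of 1000 samples)
    the decoder sees 10,000 training samples.
    """
    activity = np.asarray(activity_by_context, dtype=float)
    sources = np.asarray(sources_by_context, dtype=float)
    n_ctx = activity.shape[0]
    if n_train_ctx + n_test_ctx > n_ctx:
        raise InvalidParameterError("not enough contexts for the requested split")
    order = np.arange(n_ctx) if rng is None else rng.permutation(n_ctx)
    train_ids = list(order[:n_train_ctx])
    test_ids = list(order[n_train_ctx : n_train_ctx + n_test_ctx])
    X_train = activity[train_ids].reshape(-1, activity.shape[2])
    y_train = sources[train_ids].reshape(-1, sources.shape[2])
    model = LinearRegression().fit(X_train, y_train)
    rows = [
        {"context": int(c),
         "r2": r2_score(sources[c], model.predict(activity[c]))}
        for c in test_ids
    ]
    return DecodingReport(
        target="sources",
        decoder="linear",
        r2=pd.DataFrame(rows),
        train_contexts=[int(c) for c in train_ids],
        test_contexts=[int(c) for c in test_ids],
        n_train_samples=X_train.shape[0],
    )


def context_mean_activity(activity, context_index, second_half: bool = True):
    """Temporal average of the activity within each context; with
    ``second_half`` only the later half of each context is used, excluding
    onset transients."""
    activity = np.asarray(activity, dtype=float)
    context_index = np.asarray(context_index)
    means = []
    for ctx in np.unique(context_index):
        idx = np.flatnonzero(context_index == ctx)
        if second_half:
            idx = idx[len(idx) // 2 :]
        means.append(activity[idx].mean(axis=0))
    return np.asarray(means)


def inverse_context_targets(contexts) -> np.ndarray:
    """The four entries of A^-1 for each 2x2 context."""
    out = []
    for ctx in contexts:
        A = ctx.A if isinstance(ctx, MixingMatrix) else np.asarray(ctx)
        out.append(np.linalg.inv(A).ravel())
    return np.asarray(out)


def decode_context(
    mean_activity,
    contexts,
    mode: str = "linear",
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> DecodingReport:
    """Cross-validated decoding of the context from mean population activity.

    ``mean_activity`` is (n_contexts, n_units), one temporally averaged
    activity vector per context; ``contexts`` the matching MixingMatrix
    list (typically the 272-point grid).  ``mode``: ``linear`` regresses
    the two context variables, ``quadratic`` first augments the features
    with all squares and pairwise products, ``inverse`` regresses the four
    entries of the inverse mixing matrix.  R^2 is reported per fold of a
    ``n_folds``-fold cross-validation.
    """
    X = np.asarray(mean_activity, dtype=float)
    if len(contexts) != X.shape[0]:
        raise InvalidParameterError("one context per activity row required")
    if X.shape[0] < n_folds:
        raise InvalidParameterError("fewer contexts than folds")
    if mode == "inverse":
        targets = inverse_context_targets(contexts)
    else:
        targets = np.asarray([ctx.context_vars for ctx in contexts])
    if mode == "quadratic":
        X = PolynomialFeatures(degree=2, include_bias=False).fit_transform(X)
    seed = None if rng is None else int(rng.integers(2**31))
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(folds.split(X)):
        model = LinearRegression().fit(X[tr], targets[tr])
        rows.append({"fold": fold, "r2": r2_score(targets[te], model.predict(X[te])),
                     "test_contexts": te.tolist()})
    return DecodingReport(
        target="context" if mode != "inverse" else "inverse-context",
        decoder="quadratic-expansion" if mode == "quadratic" else "linear",
        r2=pd.DataFrame(rows),
        n_train_samples=int(round(X.shape[0] * (n_folds - 1) / n_folds)),
    )


# ---------------------------------------------------------------------------
# subspace geometry


def _readout_axes(readout: np.ndarray):
    q, _ = np.linalg.qr(np.asarray(readout, dtype=float).T)  # (N, 2) orthonormal
    return q


def subspace_coordinates(population_trace, readout, reference_trace=None):
    """Project population activity onto the two (orthonormalised) readout
    axes and the first principal component of the reference-condition
    activity after removing its components along the readout axes.

    Returns (coords, basis) with ``coords`` of shape (T, 3).
    """
    trace = np.asarray(population_trace, dtype=float)
    if np.asarray(readout).shape[0] != 2:
        raise InvalidParameterError("readout must have 2 output channels")
    if reference_trace is None:
        reference_trace = trace
    ref = np.asarray(reference_trace, dtype=float)
    q = _readout_axes(readout)
    resid = ref - (ref @ q) @ q.T
    if np.linalg.matrix_rank(np.cov(ref.T)) < 3:
        raise UndefinedMetricError("activity rank < 3: subspace axes degenerate")
    pc1 = PCA(n_components=1).fit(resid).components_[0]
    basis = np.column_stack([q, pc1])
    coords = (trace - ref.mean(axis=0)) @ basis
    return coords, basis


def fit_plane(points_3d) -> np.ndarray:
    """Total-least-squares plane through 3-D points; returns the unit
    normal (the direction of smallest variance about the centroid)."""
    pts = np.asarray(points_3d, dtype=float)
    if pts.shape[0] < 3:
        raise InvalidParameterError("need at least 3 points")
    centred = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1e-300):
        raise InvalidParameterError("points are collinear: plane fit degenerate")
    return vt[-1] / np.linalg.norm(vt[-1])


def plane_angle(normal_a, normal_b) -> float:
    """Folded angle between planes in degrees: arccos(|cos|) in [0, 90],
    so antiparallel normals give 0."""
    a = np.asarray(normal_a, dtype=float)
    b = np.asarray(normal_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InvalidParameterError("normals must be nonzero")
    c = abs(float(a @ b) / (na * nb))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def _side_label(ctx: MixingMatrix) -> int:
    a, b = ctx.context_vars
    return int(np.sign(a - b))


def angle_vs_context_distance(run_context_trace, context_pairs) -> SubspaceReport:
    """Relate context distance to the angle between activity subspaces.

    ``run_context_trace(ctx)`` must return the (T, N) population trace of
    the model under intact feedback in context ``ctx`` together with the
    (2, N) readout, i.e. a tuple ``(trace, readout)``.  For each pair the
    Euclidean distance in (a, b) context space, a same/different-side-of-
    diagonal label and the folded angle between the fitted activity planes
    are reported, with the Pearson correlation over pairs.
    """
    rows = []
    cache: dict[int, tuple] = {}

    def planes_for(ctx):
        key = id(ctx)
        if key not in cache:
            trace, readout = run_context_trace(ctx)
            cache[key] = (trace, readout)
        return cache[key]

    for ctx1, ctx2 in context_pairs:
        trace1, readout = planes_for(ctx1)
        trace2, _ = planes_for(ctx2)
        coords1, basis = subspace_coordinates(trace1, readout)
        # both traces are expressed in the basis of the first condition
        coords2 = (trace2 - trace1.mean(axis=0)) @ basis
        angle = plane_angle(fit_plane(coords1), fit_plane(coords2))
        d = float(np.linalg.norm(ctx1.context_vars - ctx2.context_vars))
        rows.append(
            {
                "distance": d,
                "angle": angle,
                "same_side": _side_label(ctx1) == _side_label(ctx2),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 2 and df["distance"].std() > 0 and df["angle"].std() > 0:
        r, p = stats.pearsonr(df["distance"], df["angle"])
    else:
        r, p = np.nan, np.nan
    return SubspaceReport(pairs=df, pearson_r=float(r), p_value=float(p))
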