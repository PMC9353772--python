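"""Intensity-based data pretreatment (IDT).

The conventional pretreatment pipeline the network profiles are benchmarked
against: missing-value imputation (one-fifth of the per-sample minimum, or
missForest-style iterative random-forest imputation), normalization (by a
reference feature such as the leucine enkephalin lock mass, or probabilistic
quotient normalization against the mean spectrum), generalized logarithm
transform and Pareto scaling.

All steps operate on :class:`~mdinet.datamodel.AlignedMatrix` and return new
matrices. :func:`idt_pipeline` chains them with the train/test leakage
guards required for cross-validated classification: test data are treated
by the same transforms with all fitted state (feature filter, glog lambda,
Pareto mean/SD, train minimum used to fill absent features) estimated on
the training portion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AlignedMatrix, filter_min_global_occurrence

__all__ = [
    "PretreatmentConfig",
    "impute_fifth_min",
    "impute_random_forest",
    "normalize_reference_feature",
    "normalize_pqn",
    "glog_transform",
    "pareto_scale",
    "idt_pipeline",
]

LEUCINE_ENKEPHALIN_MZ = 554.262022  # [M-H]- lock mass, ESI negative mode


@dataclass
class PretreatmentConfig:
    """Choices for one IDT run.

    imputation: "fifth_min" or "random_forest".
    normalization: "reference_feature" (needs ``ref_mass``) or "pqn_mean".
    glog_lambda: transform parameter; None = (global min intensity)**2.
    rf_trees / rf_similar_features: forest size and number of correlated
    predictor features for RF imputation.
    """

    imputation: str = "fifth_min"
    normalization: str = "pqn_mean"
    ref_mass: float = LEUCINE_ENKEPHALIN_MZ
    ref_tol_ppm: float = 1.0
    glog_lambda: float | None = None
    rf_trees: int = 50
    rf_similar_features: int = 100
    rf_max_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imputation not in {"fifth_min", "random_forest"}:
            raise ValueError(f"unknown imputation {self.imputation!r}")
        if self.normalization not in {"reference_feature", "pqn_mean"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_fifth_min(m: AlignedMatrix) -> AlignedMatrix:
    """Replace MISSING by one-fifth of each sample's minimum measured value."""
    x = m.intensities
    fill = x.min(axis=0, skipna=True) / 5.0
    if fill.isna().any():
        bad = list(fill.index[fill.isna()])
        raise ValueError(f"samples with no non-missing values: {bad}")
    return m.with_intensities(x.fillna(fill))


def impute_random_forest(m: AlignedMatrix, cfg: PretreatmentConfig | None = None) -> AlignedMatrix:
    """missForest-style iterative random-forest imputation.

    Missing cells are initialized by fifth-min, then each feature with
    missing values is regressed (samples as observations) on its most
    correlated features — the top ``rf_similar_features`` by absolute
    Pearson correlation on the current completed matrix — with a
    ``rf_trees``-tree forest. Iterations stop when the sum of squared
    changes of the imputed cells stops decreasing, or after
    ``rf_max_iter`` rounds. Deterministic under a fixed seed.
    """
    from sklearn.ensemble import RandomForestRegressor

    cfg = cfg or PretreatmentConfig(imputation="random_forest")
    x = m.intensities
    mask = x.isna()
    if not mask.to_numpy().any():
        return m
    filled = impute_fifth_min(m).intensities.copy()
    # features x samples -> observations are samples: work on the transpose
    data = filled.T  # samples x features
    miss = mask.T
    targets = [f for f in data.columns if miss[f].any()]
    targets.sort(key=lambda f: int(miss[f].sum()))  # least missing first
    prev_change = np.inf
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.rf_max_iter):
        change = 0.0
        corr = data.corr().abs()
        for f in targets:
            obs = ~miss[f]
            others = corr[f].drop(index=f).dropna().sort_values(ascending=False)
            preds = list(others.index[: cfg.rf_similar_features])
            if not preds:
                continue
            rf = RandomForestRegressor(
                n_estimators=cfg.rf_trees,
                random_state=int(rng.integers(2**31 - 1)),
            )
            rf.fit(data.loc[obs, preds].to_numpy(), data.loc[obs, f].to_numpy())
            new_vals = rf.predict(data.loc[~obs, preds].to_numpy())
            change += float(np.sum((new_vals - data.loc[~obs, f].to_numpy()) ** 2))
            data.loc[~obs, f] = new_vals
        if change >= prev_change:
            break
        prev_change = change
    return m.with_intensities(data.T)


def impute(m: AlignedMatrix, cfg: PretreatmentConfig) -> AlignedMatrix:
    if cfg.imputation == "fifth_min":
        return impute_fifth_min(m)
    return impute_random_forest(m, cfg)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_reference_feature(
    m: AlignedMatrix, ref_mass: float = LEUCINE_ENKEPHALIN_MZ, tol_ppm: float = 1.0
) -> AlignedMatrix:
    """Divide each sample by its intensity of a reference (lock-mass) feature.

    The feature is located by mass within ``tol_ppm`` and removed from the
    output. Exactly one candidate must match and it must be measured (or
    imputed) in every sample.
    """
    tol = ref_mass * tol_ppm * 1e-6
    hits = m.neutral_mass[(m.neutral_mass - ref_mass).abs() <= tol]
    if len(hits) == 0:
        raise ValueError(f"no feature within {tol_ppm} ppm of {ref_mass}")
    if len(hits) > 1:
        raise ValueError(
            f"multiple features within {tol_ppm} ppm of {ref_mass}: "
            f"{dict(hits.round(6))}"
        )
    ref_id = hits.index[0]
    ref = m.intensities.loc[ref_id]
    if ref.isna().any() or (ref <= 0).any():
        raise ValueError(f"reference feature {ref_id!r} missing/zero in some samples")
    out = m.intensities.div(ref, axis=1).drop(index=ref_id)
    return AlignedMatrix(out, m.neutral_mass.drop(index=ref_id), m.classes)


def normalize_pqn(m: AlignedMatrix, reference: pd.Series | None = None) -> AlignedMatrix:
    """Probabilistic quotient normalization against the mean spectrum.

    Reference = per-feature mean over samples (or a supplied spectrum, e.g.
    fitted on training data); each sample is divided by the median of its
    feature-wise quotients against the reference, over features with a
    positive reference value. Requires a complete (imputed) matrix.
    """
    x = m.intensities
    if x.isna().to_numpy().any():
        raise ValueError("PQN requires an imputed (complete) matrix")
    ref = x.mean(axis=1) if reference is None else reference.reindex(x.index)
    pos = ref > 0
    if not pos.any():
        raise ValueError("reference spectrum is nonpositive everywhere")
    quot = x.loc[pos].div(ref[pos], axis=0)
    factors = quot.median(axis=0)
    return m.with_intensities(x.div(factors, axis=1))


# ---------------------------------------------------------------------------
# transform / scaling
# ---------------------------------------------------------------------------

def glog_transform(m: AlignedMatrix, lam: float | None = None) -> AlignedMatrix:
    """Generalized logarithm g(x) = log2((x + sqrt(x^2 + lambda)) / 2).

    lambda = 0 reduces exactly to log2(x); the default lambda is the square
    of the smallest non-missing intensity (a small variance-stabilizing
    offset on the scale of the data).
    """
    x = m.intensities
    if lam is None:
        lam = float(np.nanmin(x.to_numpy())) ** 2
    if lam < 0:
        raise ValueError("glog lambda must be nonnegative")
    if lam == 0 and (x <= 0).any().any():
        raise ValueError("nonpositive intensities need lambda > 0")
    vals = np.log2((x + np.sqrt(np.square(x) + lam)) / 2.0)
    return m.with_intensities(vals)


def pareto_scale(
    m: AlignedMatrix, center: pd.Series | None = None, scale: pd.Series | None = None
) -> AlignedMatrix:
    """Per-feature mean-centering and division by sqrt(SD).

    ``center``/``scale`` (mean and sqrt-SD) may be supplied to re-apply
    parameters fitted on training data. Constant features become all-zero.
    """
    if m.n_samples < 2 and center is None:
        raise ValueError("Pareto scaling needs at least two samples")
    x = m.intensities
    mu = x.mean(axis=1) if center is None else center.reindex(x.index)
    sd = x.std(axis=1, ddof=1) if scale is None else scale.reindex(x.index)
    root = np.sqrt(sd)
    scaled = x.sub(mu, axis=0).div(root.replace(0.0, np.nan), axis=0).fillna(0.0)
    out = m.with_intensities(scaled)
    # negative values are legal after centering: bypass nonnegativity check
    return out


def pareto_parameters(m: AlignedMatrix) -> tuple[pd.Series, pd.Series]:
    """Mean and SD per feature, for leakage-safe reuse on test data."""
    return m.intensities.mean(axis=1), m.intensities.std(axis=1, ddof=1)


# ---------------------------------------------------------------------------
# full pipeline with leakage guards
# ---------------------------------------------------------------------------

@dataclass
class IdtResult:
    train: AlignedMatrix
    test: AlignedMatrix | None = None
    fitted: dict = field(default_factory=dict)


def idt_pipeline(
    train: AlignedMatrix,
    test: AlignedMatrix | None = None,
    cfg: PretreatmentConfig | None = None,
) -> IdtResult:
    """Imputation -> normalization -> glog -> Pareto, leakage-safe.

    Train-side: features are first filtered to those occurring in at least
    two training samples. Test-side rules (all fitted on train only): test
    features occurring in a single test sample are imputed by fifth-min
    rather than by the forest; features absent from the test set are filled
    with the minimum intensity observed in the training set; glog lambda and
    Pareto mean/SD come from the training data.
    """
    cfg = cfg or PretreatmentConfig()
    train = filter_min_global_occurrence(train, 2)
    fitted: dict = {}

    if test is not None:
        if not set(test.feature_ids) & set(train.feature_ids):
            raise ValueError("train and test share no features")
        test = test.select_features(
            [f for f in train.feature_ids if f in set(test.feature_ids)]
        )
        # align test to the train feature universe
        inten = test.intensities.reindex(train.feature_ids)
        train_min = float(np.nanmin(train.intensities.to_numpy()))
        absent = inten.notna().sum(axis=1) == 0
        inten.loc[absent] = train_min
        test = AlignedMatrix(inten, train.neutral_mass, test.classes)
        fitted["train_min"] = train_min

    tr = impute(train, cfg)
    if test is not None:
        if cfg.imputation == "random_forest":
            # features seen in a single test sample are too sparse for the
            # forest: their missing cells get the fifth-min rule up front,
            # the forest imputes the rest (no state shared across sets)
            inten = test.intensities
            singles = inten.notna().sum(axis=1) == 1
            if singles.any():
                fill = inten.min(axis=0, skipna=True) / 5.0
                patched = inten.copy()
                patched.loc[singles] = patched.loc[singles].fillna(fill)
                test = test.with_intensities(patched)
            te = impute_random_forest(test, cfg)
        else:
            te = impute_fifth_min(test)
    else:
        te = None

    if cfg.normalization == "reference_feature":
        tr = normalize_reference_feature(tr, cfg.ref_mass, cfg.ref_tol_ppm)
        if te is not None:
            te = normalize_reference_feature(te, cfg.ref_mass, cfg.ref_tol_ppm)
    else:
        ref = tr.intensities.mean(axis=1)
        fitted["pqn_reference"] = ref
        tr = normalize_pqn(tr)
        if te is not None:
            te = normalize_pqn(te, reference=ref)

    lam = cfg.glog_lambda
    if lam is None:
        lam = float(np.nanmin(tr.intensities.to_numpy())) ** 2
    fitted["glog_lambda"] = lam
    tr = glog_transform(tr, lam)
    if te is not None:
        te = glog_transform(te, lam)

    mu, sd = pareto_parameters(tr)
    fitted["pareto_mean"], fitted["pareto_sd"] = mu, sd
    tr = pareto_scale(tr, center=mu, scale=sd)
    if te is not None:
        te = pareto_scale(te, center=mu, scale=sd)
    return IdtResult(train=tr, test=te, fitted=fitted)
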