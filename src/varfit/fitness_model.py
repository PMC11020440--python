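"""The linear fitness model and its interpretability layer.

The predicted fitness of a single-site variant is a linear combination
of eight per-variant features — four structural-context terms (RSA and
the external predictors PoP, MAE, SNP) and four evolutionary terms
(PVS, CI, LOR, PYF):

    score = a1*RSA + a2*PoP + a3*MAE + a4*SNP
          + a5*PVS + a6*CI  + a7*LOR + a8*PYF + a9

By convention a score of 1 means mutant fitness equal to wild-type,
0 or below means a non-functional mutant, and values above 1 mean the
mutant is fitter than the wild-type.  The raw score is never clamped.

For interpretation the model is split into a structural block
``STR = a2*PoP + a3*MAE + a4*SNP`` and an evolutionary block
``EVO = a5*PVS + a6*CI + a7*LOR + a8*PYF`` (RSA and the intercept
belong to neither), and each of score/STR/EVO is turned into a z-score
over the protein's full single-site mutational landscape.  Negative
Z_evo marks substitutions rarely tolerated across evolution; negative
Z_str marks substitutions predicted to perturb the fold more than the
average mutation.

Two auxiliary single-feature models are provided: an affine rescaling
of the SNP score and a double-ReLU rescaling of the PoP score that
bounds its output to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_features import (
    FrequencyModel,
    SubstitutionMatrix,
    Variant,
    conservation_index,
    log_odds_ratio,
    provean_score,
)
from .coevolution import PottsModel, variant_delta_fitness
from .structure_features import ExternalFeatureTable

__all__ = [
    "FEATURES",
    "STRUCTURAL_BLOCK",
    "EVOLUTIONARY_BLOCK",
    "FeatureVector",
    "Coefficients",
    "FitDiagnostics",
    "TrainingSet",
    "assemble_features",
    "impute_missing",
    "fitness_score",
    "fit_coefficients",
    "rescaled_snp",
    "rescaled_pop",
    "decompose",
    "zscores",
    "per_residue_summary",
    "subset_mean",
]

#: Feature order of the linear model (alpha_1 .. alpha_8 in this order).
FEATURES: tuple[str, ...] = ("RSA", "PoP", "MAE", "SNP", "PVS", "CI", "LOR", "PYF")

#: Features entering the structural interpretability block.
STRUCTURAL_BLOCK: tuple[str, ...] = ("PoP", "MAE", "SNP")

#: Features entering the evolutionary interpretability block.
EVOLUTIONARY_BLOCK: tuple[str, ...] = ("PVS", "CI", "LOR", "PYF")


@dataclass(frozen=True)
class FeatureVector:
    """The eight per-variant features; ``None`` marks an absent value."""

    RSA: float | None = None
    PoP: float | None = None
    MAE: float | None = None
    SNP: float | None = None
    PVS: float | None = None
    CI: float | None = None
    LOR: float | None = None
    PYF: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in FEATURES:
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"feature {name} is not finite: {v}")
        ci = self.CI
        if ci is not None and ci < 0:
            raise ValueError(f"CI must be non-negative, got {ci}")

    @property
    def mask(self) -> dict[str, bool]:
        """Availability of each feature."""
        return {name: getattr(self, name) is not None for name in FEATURES}

    def as_array(self) -> np.ndarray:
        """The eight features as a float vector; absent values are an error."""
        missing = [name for name in FEATURES if getattr(self, name) is None]
        if missing:
            raise ValueError(
                f"feature(s) {', '.join(missing)} absent; run imputation first"
            )
        return np.array([getattr(self, name) for name in FEATURES], dtype=float)


@dataclass(frozen=True)
class Coefficients:
    """Fitted parameters of the linear model and the two rescalings.

    ``alpha`` holds a1..a9 (eight feature weights + intercept),
    ``beta`` the affine SNP rescaling (b1, b2) and ``gamma`` the
    clamped PoP rescaling (g1, g2).  ``provenance`` describes the
    training set the values came from.
    """

    alpha: np.ndarray
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    gamma: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    provenance: str = ""
    #: medians of the training features, used to impute a feature that is
    #: absent for *every* variant of a prediction run
    feature_medians: dict[str, float] | None = None

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if alpha.shape != (9,):
            raise ValueError("alpha must have 9 entries (8 weights + intercept)")
        if beta.shape != (2,) or gamma.shape != (2,):
            raise ValueError("beta and gamma must each have 2 entries")
        for name, arr in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "feature_order": list(FEATURES),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "provenance": self.provenance,
            "feature_medians": self.feature_medians,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Coefficients":
        payload = json.loads(Path(path).read_text())
        if payload.get("feature_order") != list(FEATURES):
            raise ValueError(
                f"{path}: feature order {payload.get('feature_order')} does not "
                f"match this package's {list(FEATURES)}"
            )
        return cls(
            alpha=np.array(payload["alpha"], dtype=float),
            beta=np.array(payload["beta"], dtype=float),
            gamma=np.array(payload["gamma"], dtype=float),
            provenance=payload.get("provenance", ""),
            feature_medians=payload.get("feature_medians"),
        )


@dataclass(frozen=True)
class TrainingSet:
    """Variants with complete features and experimental fitness values.

    ``table`` columns: protein, position, wt, mt, the eight feature
    columns, fitness.  Duplicate (protein, variant) pairs are rejected.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["protein", "position", "wt", "mt", "fitness"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"training table lacks column(s): {missing}")
        keys = self.table[["protein", "position", "wt", "mt"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise ValueError("training table contains duplicate (protein, variant) pairs")
        if not np.all(np.isfinite(self.table["fitness"].astype(float))):
            raise ValueError("training fitness values must be finite")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature assembly and imputation
# ---------------------------------------------------------------------------


def assemble_features(
    variant: Variant,
    frequencies: FrequencyModel | None = None,
    potts: PottsModel | None = None,
    substitution_matrix: SubstitutionMatrix | None = None,
    rsa_by_position: dict[int, float] | None = None,
    external: ExternalFeatureTable | None = None,
) -> FeatureVector:
    """Collect the eight features of one variant from their sources.

    Evolutionary features come from the frequency model's MSA (CI, LOR,
    PVS) and the Potts model (PYF); RSA comes from a per-query-position
    lookup already mapped through the structure; PoP/MAE/SNP come from
    an external feature table.  Absent sources leave features absent —
    nothing is imputed here.  Undefined PVS/PYF (uncovered columns) are
    recorded in ``flags``.
    """
    values: dict[str, float | None] = {name: None for name in FEATURES}
    flags: list[str] = []

    if frequencies is not None:
        msa = frequencies.msa
        col = msa.check_variant(variant)
        values["CI"] = conservation_index(frequencies, col)
        values["LOR"] = log_odds_ratio(frequencies, variant)
        pvs = provean_score(msa, variant, substitution_matrix)
        values["PVS"] = pvs.value
        if not pvs.defined:
            flags.append("PVS_uncovered")
        if potts is not None:
            if potts.N != msa.N:
                raise ValueError(
                    f"Potts model length {potts.N} does not match MSA length {msa.N}"
                )
            pyf = variant_delta_fitness(potts, msa.codes[0], variant)
            values["PYF"] = pyf.value
            if not pyf.defined:
                flags.append("PYF_uncovered")

    if rsa_by_position is not None:
        rsa = rsa_by_position.get(variant.position)
        if rsa is None:
            flags.append("RSA_unmapped")
        else:
            values["RSA"] = float(rsa)

    if external is not None:
        for name in ("PoP", "MAE", "SNP"):
            values[name] = external.get(variant, name)

    return FeatureVector(**values, flags=tuple(flags))


def impute_missing(table: pd.DataFrame, features: tuple[str, ...] = FEATURES
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute absent feature values over a per-protein table.

    Each feature's missing entries are replaced by the median of its
    present values in the same table.  Returns the completed table and
    a same-shaped boolean mask of which cells were imputed.  A feature
    absent everywhere cannot be imputed and is an error.
    """
    out = table.copy()
    for f in features:
        if f not in out.columns:
            out[f] = np.nan
    imputed = out[list(features)].isna()
    for f in features:
        col = out[f].astype(float)
        if col.isna().all():
            raise ValueError(f"feature {f!r} is absent for every variant; cannot impute")
        out[f] = col.fillna(float(col.median()))
    return out, imputed


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def fitness_score(fv: FeatureVector | np.ndarray, coef: Coefficients) -> float:
    """Raw linear fitness score of one variant (unclamped)."""
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    return float(x @ coef.alpha[:8] + coef.alpha[8])


def rescaled_snp(snp: float, coef: Coefficients) -> float:
    """Affine rescaling of the SNP deleteriousness score: b1*SNP + b2."""
    return float(coef.beta[0] * snp + coef.beta[1])


def _relu(x: float) -> float:
    return x if x > 0.0 else 0.0


def rescaled_pop(pop: float, coef: Coefficients) -> float:
    """Double-ReLU rescaling of the PoP stability score, bounded to [0, 1].

    Computed literally as ``-ReLU(-ReLU(g1*PoP + g2) + 1) + 1``, which
    is algebraically the clamp of ``g1*PoP + g2`` to [0, 1].
    """
    y = coef.gamma[0] * pop + coef.gamma[1]
    return float(-_relu(-_relu(y) + 1.0) + 1.0)


def decompose(fv: FeatureVector | np.ndarray, coef: Coefficients) -> tuple[float, float]:
    """Structural and evolutionary contributions (STR, EVO) of a variant.

    ``STR + EVO + a1*RSA + a9`` reconstructs the full score; RSA and
    the intercept belong to neither block.
    """
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    a = coef.alpha
    str_part = a[1] * x[1] + a[2] * x[2] + a[3] * x[3]
    evo_part = a[4] * x[4] + a[5] * x[5] + a[6] * x[6] + a[7] * x[7]
    return float(str_part), float(evo_part)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitDiagnostics:
    """Summary of a coefficient fit.

    ``evo_str_ratio`` compares the blocks' standardized weights
    (sum of |alpha_j| * sd(feature_j) over the evolutionary block
    divided by the same sum over the structural block) — the
    diagnostic of how much more predictive power the evolutionary
    terms carry.
    """

    residual_rms: float
    stderr: np.ndarray            # standard error of each alpha
    evo_str_ratio: float
    n: int
    method: str


def fit_coefficients(
    train: TrainingSet,
    method: str = "ols",
    ridge_penalty: float = 1e-6,
) -> tuple[Coefficients, FitDiagnostics]:
    """Least-squares fit of the linear model to experimental fitness.

    ``method="ols"`` solves the plain normal equations and raises on a
    rank-deficient design (recommending ridge); ``method="ridge"`` adds
    a small L2 penalty on the eight feature weights (never on the
    intercept).  Features are used on their native scales — no
    standardization is applied to the fit itself; standardized weights
    appear only in the diagnostics.
    """
    if method not in ("ols", "ridge"):
        raise ValueError(f"unknown method {method!r}")
    df = train.table
    missing = [f for f in FEATURES if f not in df.columns]
    if missing:
        raise ValueError(f"training table lacks feature column(s): {missing}")
    if df[list(FEATURES)].isna().any().any():
        raise ValueError("training features contain missing values; impute first")
    n = len(df)
    if n < 9:
        raise ValueError(f"need at least 9 training rows, got {n}")

    X = np.column_stack([df[list(FEATURES)].to_numpy(dtype=float), np.ones(n)])
    y = df["fitness"].to_numpy(dtype=float)

    if method == "ols":
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                "use method='ridge'"
            )
        alpha, *_ = np.linalg.lstsq(X, y, rcond=None)
        xtx_inv = np.linalg.inv(X.T @ X)
    else:
        penalty = ridge_penalty * np.eye(X.shape[1])
        penalty[-1, -1] = 0.0  # leave the intercept unpenalized
        A = X.T @ X + penalty
        alpha = np.linalg.solve(A, X.T @ y)
        xtx_inv = np.linalg.inv(A)

    residuals = y - X @ alpha
    dof = max(n - X.shape[1], 1)
    sigma2 = float(residuals @ residuals) / dof
    stderr = np.sqrt(sigma2 * np.diag(xtx_inv))

    sds = df[list(FEATURES)].to_numpy(dtype=float).std(axis=0)
    std_weight = np.abs(alpha[:8]) * sds
    str_idx = [FEATURES.index(f) for f in STRUCTURAL_BLOCK]
    evo_idx = [FEATURES.index(f) for f in EVOLUTIONARY_BLOCK]
    str_sum = float(std_weight[str_idx].sum())
    evo_sum = float(std_weight[evo_idx].sum())
    ratio = evo_sum / str_sum if str_sum > 0 else np.inf

    proteins = sorted(df["protein"].astype(str).unique())
    coef = Coefficients(
        alpha=alpha,
        provenance=f"{method} fit on {n} variants of {', '.join(proteins)}",
        feature_medians={f: float(df[f].median()) for f in FEATURES},
    )
    diag = FitDiagnostics(
        residual_rms=float(np.sqrt(np.mean(residuals ** 2))),
        stderr=stderr,
        evo_str_ratio=ratio,
        n=n,
        method=method,
    )
    return coef, diag


# ---------------------------------------------------------------------------
# Z-scores over the mutational landscape
# ---------------------------------------------------------------------------

_Z_SOURCES = {"Z": "score", "Z_str": "STR", "Z_evo": "EVO"}


def zscores(table: pd.DataFrame, query_length: int | None = None) -> pd.DataFrame:
    """Standardize score/STR/EVO over all mutations of one protein.

    ``Z = (x - mean(x)) / sd(x)`` with the population standard
    deviation (the landscape is the whole population, not a sample).
    The mean and sd are meant to be taken over the complete single-site
    landscape (19 substitutions at each of L positions); passing
    ``query_length`` enables a warning when only a subset is scored.
    Constant scores make the z-score undefined and raise.
    """
    for col in ("score", "STR", "EVO"):
        if col not in table.columns:
            raise ValueError(f"score table lacks column {col!r}")
    if query_length is not None and len(table) != 19 * query_length:
        warnings.warn(
            f"z-scores computed over {len(table)} variants, not the full "
            f"landscape of {19 * query_length}; interpret with care",
            stacklevel=2,
        )
    out = table.copy()
    for zcol, src in _Z_SOURCES.items():
        x = out[src].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std()  # population sd (ddof=0)
        if sd == 0.0:
            raise ValueError(f"{src} is constant over the table; z-score undefined")
        out[zcol] = (x - mu) / sd
    return out


def per_residue_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean z-scores over the substitutions of each residue position."""
    if table.empty:
        raise ValueError("empty score table")
    cols = [c for c in ("Z", "Z_str", "Z_evo") if c in table.columns]
    if not cols:
        raise ValueError("score table has no z-score columns; run zscores first")
    return table.groupby("position", sort=True)[cols].mean().reset_index()


def subset_mean(table: pd.DataFrame, mask, column: str = "Z") -> float:
    """Mean of one z-score column over a subset of variants.

    Used e.g. to summarize gain-of-function variants (those whose
    experimental fitness exceeds the wild-type's).
    """
    sub = table.loc[mask, column]
    if len(sub) == 0:
        raise ValueError("subset is empty; its mean is undefined")
    return float(sub.mean())
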