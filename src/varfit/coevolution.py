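"""Potts-model coevolution scoring by pseudo-likelihood maximization.

A pairwise Markov random field (Potts model) over the alignment columns
assigns each aligned sequence ``s`` the statistical energy

    E(s) = - sum_i h_i(s_i) - sum_{i<j} J_ij(s_i, s_j)

with per-column fields ``h`` and pairwise couplings ``J`` over q = 21
states (20 amino acids + gap; gaps are kept as an ordinary state, as is
common DCA practice for alignments that contain them).  The model is
inferred from a sequence-reweighted MSA by maximizing the L2-regularized
pseudo-likelihood — the product of per-column conditional likelihoods —
site by site (asymmetric fit), followed by coupling symmetrization and
conversion to the zero-sum gauge.

The per-variant coevolutionary score is the statistical-energy change

    PYF = E(wt) - E(mt)

so that a substitution the model disfavors gives a negative score
(fitness loss).  PYF is reported in raw energy units; any downstream
linear model absorbs the scale through its fitted coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment_features import MSA, FlaggedScore, Variant
from .alphabet import GAP_INDEX, N_STATES, encode_sequence

__all__ = [
    "PottsModel",
    "SequenceWeights",
    "ConvergenceError",
    "sequence_weights",
    "fit_potts_plm",
    "sequence_energy",
    "variant_delta_fitness",
    "zero_sum_gauge",
    "random_gauge_transform",
]

DEFAULT_REWEIGHT_THRESHOLD = 0.8
DEFAULT_LAMBDA_H = 0.01


class ConvergenceError(RuntimeError):
    """Pseudo-likelihood optimization failed to converge; carries diagnostics."""


@dataclass(frozen=True)
class SequenceWeights:
    """Per-row reweighting that downweights redundant sequences.

    Each row's weight is the reciprocal of the number of rows (itself
    included) whose fractional identity to it is at least the
    threshold, so 0 < w_k <= 1 and the effective depth is sum(w).
    """

    weights: np.ndarray
    threshold: float

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


def sequence_weights(msa: MSA, threshold: float = DEFAULT_REWEIGHT_THRESHOLD) -> SequenceWeights:
    """Compute identity-based sequence weights for an MSA."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"identity threshold must lie in (0, 1], got {threshold}")
    codes = msa.codes
    m = codes.shape[0]
    counts = np.zeros(m, dtype=np.int64)
    # pairwise fractional identity over all columns, gaps compared like states
    for k in range(m):
        ident = (codes == codes[k]).mean(axis=1)
        counts[k] = int((ident >= threshold).sum())
    return SequenceWeights(weights=1.0 / counts, threshold=threshold)


@dataclass(frozen=True)
class PottsModel:
    """Fields and couplings of a Potts model over N columns and q states.

    ``J`` is stored as a full (N, N, q, q) array with the symmetry
    ``J[i, j, a, b] == J[j, i, b, a]`` and zero diagonal blocks; the
    energy sums each unordered pair once.
    """

    h: np.ndarray                     # (N, q)
    J: np.ndarray                     # (N, N, q, q)
    lambda_h: float = 0.0
    lambda_J: float = 0.0
    reweight_threshold: float = DEFAULT_REWEIGHT_THRESHOLD
    homolog_coverage: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        J = np.asarray(self.J, dtype=float)
        N, q = h.shape
        if J.shape != (N, N, q, q):
            raise ValueError(f"J shape {J.shape} does not match h shape {h.shape}")
        if not np.allclose(J, np.transpose(J, (1, 0, 3, 2)), atol=1e-8):
            raise ValueError("couplings must satisfy J[i,j,a,b] == J[j,i,b,a]")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "J", J)

    @property
    def N(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a self-describing NumPy ``.npz`` container."""
        meta = np.array(
            [self.lambda_h, self.lambda_J, self.reweight_threshold], dtype=float
        )
        cov = self.homolog_coverage
        np.savez_compressed(
            path,
            format_version=np.array([1]),
            h=self.h,
            J=self.J,
            meta=meta,
            homolog_coverage=cov if cov is not None else np.array([]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PottsModel":
        with np.load(path) as data:
            cov = data["homolog_coverage"]
            return cls(
                h=data["h"],
                J=data["J"],
                lambda_h=float(data["meta"][0]),
                lambda_J=float(data["meta"][1]),
                reweight_threshold=float(data["meta"][2]),
                homolog_coverage=cov if cov.size else None,
            )


def zero_sum_gauge(h: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert fields and couplings to the zero-sum (Ising) gauge.

    In the result every coupling block and every field sums to zero
    over states; sequence energies change only by a sequence-independent
    constant, so all energy differences are preserved.
    """
    h = h.astype(float).copy()
    J = J.astype(float).copy()
    N = h.shape[0]
    for i in range(N):
        for j in range(i + 1, N):
            K = J[i, j]
            rm = K.mean(axis=1)
            cm = K.mean(axis=0)
            mm = K.mean()
            K0 = K - rm[:, None] - cm[None, :] + mm
            J[i, j] = K0
            J[j, i] = K0.T
            h[i] += rm - mm
            h[j] += cm - mm
    h -= h.mean(axis=1, keepdims=True)
    return h, J


def random_gauge_transform(model: PottsModel, rng: np.random.Generator,
                           scale: float = 1.0) -> PottsModel:
    """Apply a random energy-preserving reparameterization.

    For every pair (i, j) an arbitrary per-state shift is added to the
    coupling rows/columns and subtracted from the matching fields; all
    sequence energies change by at most a global constant, so variant
    scores are untouched.  Used to verify gauge invariance.
    """
    h = model.h.copy()
    J = model.J.copy()
    N, q = model.N, model.q
    for i in range(N):
        for j in range(i + 1, N):
            u = rng.normal(scale=scale, size=q)
            v = rng.normal(scale=scale, size=q)
            J[i, j] = J[i, j] + u[:, None] + v[None, :]
            J[j, i] = J[i, j].T
            h[i] -= u
            h[j] -= v
    return PottsModel(
        h=h, J=J, lambda_h=model.lambda_h, lambda_J=model.lambda_J,
        reweight_threshold=model.reweight_threshold,
        homolog_coverage=model.homolog_coverage,
    )


def _site_objective(x, site, S, w, lam_h, lam_J, q):
    """Weighted negative log-pseudo-likelihood for one column + gradient."""
    m, N = S.shape
    W = w.sum()
    h = x[:q]
    Jr = x[q:].reshape(N - 1, q, q)
    others = [j for j in range(N) if j != site]

    logits = np.tile(h, (m, 1))
    for idx, j in enumerate(others):
        logits += Jr[idx][:, S[:, j]].T
    lse = logsumexp(logits, axis=1)
    ll = logits[np.arange(m), S[:, site]] - lse
    nll = -(w * ll).sum() / W

    P = np.exp(logits - lse[:, None])
    D = P.copy()
    D[np.arange(m), S[:, site]] -= 1.0
    D *= w[:, None] / W
    grad_h = D.sum(axis=0)
    grad_J = np.zeros_like(Jr)
    for idx, j in enumerate(others):
        acc = np.zeros((q, q))            # acc[b, a] = sum over rows with S[:,j]==b
        np.add.at(acc, S[:, j], D)
        grad_J[idx] = acc.T

    nll += lam_h * (h ** 2).sum() + lam_J * (Jr ** 2).sum()
    grad_h += 2.0 * lam_h * h
    grad_J += 2.0 * lam_J * Jr
    return nll, np.concatenate([grad_h, grad_J.ravel()])


def fit_potts_plm(
    msa: MSA,
    weights: SequenceWeights | None = None,
    lambda_h: float = DEFAULT_LAMBDA_H,
    lambda_J: float | None = None,
    gtol: float = 1e-5,
    max_iter: int = 2000,
    q: int = N_STATES,
) -> PottsModel:
    """Infer a Potts model from an MSA by pseudo-likelihood maximization.

    Each column's conditional likelihood is maximized independently
    (asymmetric fit) with L-BFGS from a zero initialization, which makes
    the result deterministic; the two estimates of every coupling block
    are then averaged and the model is reported in the zero-sum gauge.

    ``lambda_J`` defaults to ``0.01 * (N - 1)``, the usual plmDCA-style
    scaling that keeps the per-pair penalty constant as the number of
    potential partners grows.  The weighted data term is normalized by
    the effective depth, so the regularization strength does not depend
    on alignment size.
    """
    if msa.m < 2:
        raise ValueError("Potts inference needs at least 2 sequences")
    N = msa.N
    if int(msa.codes.max()) >= q:
        raise ValueError(
            f"alignment uses state {int(msa.codes.max())} but the model has q={q}"
        )
    if lambda_J is None:
        lambda_J = 0.01 * (N - 1)
    if lambda_h <= 0 or lambda_J <= 0:
        raise ValueError("regularization strengths must be positive and finite")
    if weights is None:
        weights = sequence_weights(msa)
    w = np.asarray(weights.weights, dtype=float)
    S = msa.codes.astype(np.int64)

    h = np.zeros((N, q))
    J_dir = np.zeros((N, N, q, q))    # J_dir[i, j] = estimate of J_ij from site i's fit
    for site in range(N):
        n_par = q + (N - 1) * q * q
        res = minimize(
            _site_objective,
            np.zeros(n_par),
            args=(site, S, w, lambda_h, lambda_J, q),
            method="L-BFGS-B",
            jac=True,
            options={"gtol": gtol, "maxiter": max_iter, "ftol": 1e-12},
        )
        if not res.success:
            raise ConvergenceError(
                f"site {site}: {res.message} after {res.nit} iterations, "
                f"|grad|={np.abs(res.jac).max():.3e}"
            )
        h[site] = res.x[:q]
        Jr = res.x[q:].reshape(N - 1, q, q)
        others = [j for j in range(N) if j != site]
        for idx, j in enumerate(others):
            J_dir[site, j] = Jr[idx]

    # symmetrize: average the two independent estimates of each block
    J = np.zeros_like(J_dir)
    for i in range(N):
        for j in range(i + 1, N):
            K = 0.5 * (J_dir[i, j] + J_dir[j, i].T)
            J[i, j] = K
            J[j, i] = K.T
    h, J = zero_sum_gauge(h, J)

    coverage = (msa.codes[1:] != GAP_INDEX).sum(axis=0) if msa.m > 1 else np.zeros(N, int)
    return PottsModel(
        h=h, J=J, lambda_h=lambda_h, lambda_J=lambda_J,
        reweight_threshold=weights.threshold,
        homolog_coverage=coverage.astype(np.int64),
    )


def _as_codes(seq: str | np.ndarray, N: int) -> np.ndarray:
    codes = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int64)
    if codes.shape != (N,):
        raise ValueError(f"sequence length {codes.shape[0]} does not match model length {N}")
    return codes.astype(np.int64)


def sequence_energy(model: PottsModel, seq: str | np.ndarray) -> float:
    """Statistical energy ``E(s) = -sum h - sum_{i<j} J`` of one sequence."""
    s = _as_codes(seq, model.N)
    e = -model.h[np.arange(model.N), s].sum()
    for i in range(model.N):
        for j in range(i + 1, model.N):
            e -= model.J[i, j, s[i], s[j]]
    return float(e)


def variant_delta_fitness(
    model: PottsModel,
    wt_seq: str | np.ndarray,
    variant: Variant,
) -> FlaggedScore:
    """Coevolutionary variant score ``PYF = E(wt) - E(mt)``.

    ``wt_seq`` is the aligned query row of the MSA the model was fit
    on; the variant's 1-based position indexes the ungapped query.  The
    single-site change is evaluated incrementally in O(N) rather than
    by re-summing both energies.  A column never covered by any homolog
    carries no coevolutionary information, so the score is 0 with
    ``defined=False``.
    """
    s = _as_codes(wt_seq, model.N)
    residue_cols = np.flatnonzero(s != GAP_INDEX)
    if not 1 <= variant.position <= residue_cols.size:
        raise IndexError(
            f"variant position {variant.position} outside query length {residue_cols.size}"
        )
    col = int(residue_cols[variant.position - 1])
    wt_code = int(encode_sequence(variant.wt)[0])
    mt_code = int(encode_sequence(variant.mt)[0])
    if s[col] != wt_code:
        raise ValueError(
            f"variant {variant} conflicts with the model's query sequence at "
            f"position {variant.position}"
        )
    if model.homolog_coverage is not None and model.homolog_coverage[col] == 0:
        return FlaggedScore(0.0, False)

    # E(wt) - E(mt): only terms touching `col` differ
    delta = model.h[col, mt_code] - model.h[col, wt_code]
    other = np.flatnonzero(np.arange(model.N) != col)
    delta += (model.J[col, other, mt_code, s[other]]
              - model.J[col, other, wt_code, s[other]]).sum()
    return FlaggedScore(float(delta), True)
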