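"""Generators for every input the prediction pipeline consumes.

All generators are deterministic functions of an integer seed: each
public function creates its own ``numpy.random.Generator`` at entry
(no shared stream), so adding one generator call never shifts the
draws of another.  The generators produce:

* profile MSAs with independent columns (Dirichlet column profiles),
  for testing conservation and frequency scores;
* MSAs sampled *exactly* from a known Potts model by full state
  enumeration, the ground-truth oracle for coevolution inference
  (a Gibbs sampler is available for sizes beyond enumeration and is
  clearly labelled approximate);
* schematic toy structures (poly-alanine helix or extended chain,
  extended Gly-X-Gly tripeptides, multi-chain assemblies, buried-site
  constructs) written as valid PDB text;
* synthetic deep-mutational-scanning training tables whose fitness is
  an exact linear function of the features plus Gaussian noise, with
  the generating coefficients recorded.

None of the MSA generators model phylogenetic correlation between
rows; sequences are exchangeable.  That limitation is intentional:
ground truth must stay analytically known.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, GAP_INDEX, N_STATES
from .alignment_features import MSA
from .coevolution import PottsModel, zero_sum_gauge
from .fitness_model import FEATURES, Coefficients, TrainingSet

__all__ = [
    "GeneratorConfig",
    "sample_profile_msa",
    "sample_potts_msa",
    "make_toy_structure",
    "make_gly_x_gly",
    "make_assembly",
    "make_buried_site",
    "make_synthetic_dms",
    "DEFAULT_TRUE_ALPHA",
    "enumerate_states",
    "boltzmann_distribution",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of sizes and distribution parameters for fixture generation.

    Defaults are the study conditions used throughout the test suite:
    a 200-row, 30-column MSA of moderate conservation, a 30-residue
    helix, and a 2000-variant training table with noise sd 0.1.
    """

    seed: int = 0
    m: int = 200
    n_columns: int = 30
    n_residues: int = 30
    concentration: float = 0.5
    gap_fraction: float = 0.05
    n_train: int = 2000
    noise_sd: float = 0.1


# ---------------------------------------------------------------------------
# Profile MSAs
# ---------------------------------------------------------------------------


def sample_profile_msa(
    m: int,
    N: int,
    seed: int,
    concentration: float = 0.5,
    gap_fraction: float = 0.0,
    query_id: str = "query",
) -> tuple[MSA, np.ndarray]:
    """Sample an MSA with independent columns from Dirichlet profiles.

    Each column's amino-acid profile is drawn from a symmetric
    Dirichlet with the given concentration (small values give
    near-single-residue columns, large values near-uniform ones);
    homolog rows then add a constant per-state gap probability.  The
    query row is drawn last, gap-free, and placed first.  Returns the
    MSA and the (N, 21) per-column state profile actually used for the
    homolog rows.
    """
    if m < 1 or N < 1:
        raise ValueError("m and N must be at least 1")
    if concentration <= 0 or not np.isfinite(concentration):
        raise ValueError(f"Dirichlet concentration must be positive, got {concentration}")
    if not 0.0 <= gap_fraction < 1.0:
        raise ValueError("gap fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    aa_profiles = rng.dirichlet(np.full(20, concentration), size=N)  # (N, 20)
    profiles = np.zeros((N, N_STATES))
    profiles[:, :20] = aa_profiles * (1.0 - gap_fraction)
    profiles[:, GAP_INDEX] = gap_fraction

    codes = np.empty((m, N), dtype=np.int8)
    for i in range(N):
        codes[1:, i] = rng.choice(N_STATES, size=m - 1, p=profiles[i])
    # query drawn last, without gaps
    for i in range(N):
        codes[0, i] = rng.choice(20, p=aa_profiles[i])
    ids = (query_id,) + tuple(f"homolog_{k}" for k in range(1, m))
    return MSA(ids=ids, codes=codes), profiles


# ---------------------------------------------------------------------------
# Potts-model MSAs (exact enumeration oracle)
# ---------------------------------------------------------------------------

ENUMERATION_LIMIT = 10 ** 6


def enumerate_states(N: int, q: int) -> np.ndarray:
    """All q^N state vectors, lexicographic order, shape (q^N, N)."""
    return np.array(list(itertools.product(range(q), repeat=N)), dtype=np.int64)


def boltzmann_distribution(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact Boltzmann distribution of a small Potts model.

    Returns (states, probabilities) over the full enumeration; the
    probability of state s is proportional to exp(-E(s)).
    """
    N, q = model.N, model.q
    if q ** N > ENUMERATION_LIMIT:
        raise ValueError(
            f"q^N = {q ** N} exceeds the enumeration limit {ENUMERATION_LIMIT}; "
            "use the Gibbs mode"
        )
    states = enumerate_states(N, q)
    energies = model.h[np.arange(N), states].sum(axis=1)
    for i in range(N):
        for j in range(i + 1, N):
            energies += model.J[i, j][states[:, i], states[:, j]]
    energies = -energies  # E = -(sum h + sum J)
    logp = -energies - (-energies).max()
    p = np.exp(logp)
    p /= p.sum()
    return states, p


def _random_potts(N: int, q: int, rng: np.random.Generator,
                  field_scale: float, coupling_scale: float) -> PottsModel:
    h = rng.normal(scale=field_scale, size=(N, q))
    J = np.zeros((N, N, q, q))
    for i in range(N):
        for j in range(i + 1, N):
            K = rng.normal(scale=coupling_scale, size=(q, q))
            J[i, j] = K
            J[j, i] = K.T
    h, J = zero_sum_gauge(h, J)
    return PottsModel(h=h, J=J)


def sample_potts_msa(
    m: int,
    N: int,
    q: int,
    seed: int,
    field_scale: float = 0.5,
    coupling_scale: float = 0.5,
    mode: str = "exact",
    model: PottsModel | None = None,
    burn_in: int = 500,
    thin: int = 10,
) -> tuple[MSA, PottsModel]:
    """Sample an MSA from a (random or given) Potts model.

    In the default exact mode all ``q^N`` states are enumerated and
    rows are i.i.d. draws from the normalized Boltzmann distribution —
    the sampler is an oracle, not an approximation.  The Gibbs mode
    (single-site heat-bath sweeps with the stated burn-in and thinning)
    exists for sizes beyond the enumeration limit and is approximate:
    do not use it where ground truth matters.  The generating model is
    returned in the zero-sum gauge.
    """
    if q > N_STATES:
        raise ValueError(f"q cannot exceed {N_STATES}")
    rng = np.random.default_rng(seed)
    if model is None:
        model = _random_potts(N, q, rng, field_scale, coupling_scale)
    if mode == "exact":
        if q ** N > ENUMERATION_LIMIT:
            raise ValueError(
                f"q^N = {q ** N} exceeds the enumeration limit; mode='gibbs' "
                "is available but approximate"
            )
        states, p = boltzmann_distribution(model)
        picks = rng.choice(states.shape[0], size=m, p=p)
        codes = states[picks].astype(np.int8)
    elif mode == "gibbs":
        codes = _gibbs_sample(model, m, rng, burn_in, thin)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    ids = ("query",) + tuple(f"sample_{k}" for k in range(1, m))
    return MSA(ids=ids, codes=codes), model


def _gibbs_sample(model: PottsModel, m: int, rng: np.random.Generator,
                  burn_in: int, thin: int) -> np.ndarray:
    N, q = model.N, model.q
    s = rng.integers(0, q, size=N)
    out = np.empty((m, N), dtype=np.int8)
    kept = 0
    sweep = 0
    while kept < m:
        for i in range(N):
            logits = model.h[i].copy()
            for j in range(N):
                if j != i:
                    logits += model.J[i, j][:, s[j]]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            s[i] = rng.choice(q, p=p)
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            out[kept] = s
            kept += 1
    return out


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}{resid:>4d}"
    "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def _format_atom(serial, name, res, chain, resid, xyz, elem) -> str:
    pdb_name = f" {name}" if len(name) < 4 else name
    return _PDB_ATOM.format(
        serial=serial, name=pdb_name, alt=" ", res=res, chain=chain,
        resid=resid, icode=" ", x=xyz[0], y=xyz[1], z=xyz[2],
        occ=1.0, b=0.0, elem=elem,
    )


def _backbone_positions(n_res: int, conformation: str) -> np.ndarray:
    """CA trace of an idealized chain: alpha-helix or extended strand."""
    idx = np.arange(n_res)
    if conformation == "helix":
        # 100 degrees per residue, 1.5 A rise, 2.3 A radius: CA-CA ~ 3.8 A
        theta = np.deg2rad(100.0) * idx
        return np.column_stack([
            2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx,
        ])
    if conformation == "extended":
        # zigzag strand with exact 3.8 A CA-CA spacing
        y = 0.45 * (-1.0) ** idx
        x = np.sqrt(3.8 ** 2 - (2 * 0.45) ** 2) * idx
        return np.column_stack([x, y, np.zeros(n_res)])
    raise ValueError(f"unknown conformation {conformation!r}")


def _chain_pdb_records(residues, ca, chain: str, first_serial: int = 1) -> str:
    """Emit N/CA/C/O(/CB) records for a CA trace with schematic geometry."""
    n_res = len(residues)
    lines = []
    serial = first_serial
    for i, res in enumerate(residues):
        c = ca[i]
        prev_ca = ca[i - 1] if i > 0 else c - np.array([3.8, 0.0, 0.0])
        next_ca = ca[i + 1] if i < n_res - 1 else c + np.array([3.8, 0.0, 0.0])
        d = next_ca - prev_ca
        d = d / np.linalg.norm(d)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        n_vec = np.cross(d, ref)
        n_vec /= np.linalg.norm(n_vec)
        b_vec = np.cross(d, n_vec)
        atoms = [
            ("N", "N", c - 1.2 * d + 0.8 * n_vec),
            ("CA", "C", c),
            ("C", "C", c + 1.2 * d + 0.8 * n_vec),
            ("O", "O", c + 1.4 * d + 1.9 * n_vec),
        ]
        if res != "GLY":
            atoms.append(("CB", "C", c + 1.3 * b_vec - 0.6 * n_vec))
        for name, elem, xyz in atoms:
            lines.append(_format_atom(serial, name, res, chain, i + 1, xyz, elem))
            serial += 1
    return "".join(lines)


def make_toy_structure(
    n_res: int,
    conformation: str = "helix",
    res_name: str = "ALA",
    chain: str = "A",
    sequence: str | None = None,
) -> str:
    """PDB text of an idealized single-chain peptide.

    Residues carry the five heavy backbone atoms N, CA, C, O, CB
    (glycine omits CB) on a schematic geometry whose CA-CA spacing is
    the canonical 3.8 Å; side chains beyond CB are not modelled.
    ``sequence`` (one-letter codes) overrides the uniform residue type.
    """
    from .alphabet import ONE_TO_THREE

    if sequence is not None:
        residues = [ONE_TO_THREE[c.upper()] for c in sequence]
        n_res = len(residues)
    else:
        residues = [res_name] * n_res
    if n_res < 1:
        raise ValueError("need at least one residue")
    ca = _backbone_positions(n_res, conformation)
    body = _chain_pdb_records(residues, ca, chain)
    return body + "END\n"


def make_gly_x_gly(x: str, conformation: str = "extended") -> str:
    """PDB text of a Gly-X-Gly tripeptide (X at backbone+CB detail)."""
    from .alphabet import ONE_TO_THREE

    if x.upper() not in ONE_TO_THREE:
        raise ValueError(f"unknown residue {x!r}")
    residues = ["GLY", ONE_TO_THREE[x.upper()], "GLY"]
    ca = _backbone_positions(3, conformation)
    return _chain_pdb_records(residues, ca, "A") + "END\n"


def make_assembly(
    n_res: int,
    n_chains: int,
    spacing: float = 5.0,
    conformation: str = "extended",
    res_name: str = "ALA",
) -> str:
    """PDB text of ``n_chains`` parallel copies of a toy chain.

    Copies are translated by ``spacing`` Å along z so that, for small
    spacings, chains occlude one another — the fixture for
    multimer-context accessibility tests.
    """
    if n_chains < 1 or n_chains > 26:
        raise ValueError("n_chains must be between 1 and 26")
    ca0 = _backbone_positions(n_res, conformation)
    parts = []
    serial = 1
    for k in range(n_chains):
        chain_id = chr(ord("A") + k)
        ca = ca0 + np.array([0.0, 0.0, spacing * k])
        body = _chain_pdb_records([res_name] * n_res, ca, chain_id, serial)
        serial += body.count("ATOM")
        parts.append(body)
        parts.append("TER\n")
    return "".join(parts) + "END\n"


def make_buried_site(n_shell: int = 400, radius: float = 6.0) -> str:
    """PDB text of one central residue enclosed by a dense atom shell.

    The central alanine sits at the origin; chain B carries a
    two-layer Fibonacci-sphere shell of glycine CA pseudo-atoms that
    fully encloses it, so the central residue's accessibility must be
    near zero.
    """
    lines = []
    serial = 1
    center = np.zeros(3)
    for name, elem, off in [
        ("N", "N", [-1.2, 0.8, 0.0]), ("CA", "C", [0.0, 0.0, 0.0]),
        ("C", "C", [1.2, 0.8, 0.0]), ("O", "O", [1.4, 1.9, 0.0]),
        ("CB", "C", [0.0, -0.9, 1.2]),
    ]:
        lines.append(_format_atom(serial, name, "ALA", "A", 1, center + off, elem))
        serial += 1
    lines.append("TER\n")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    resid = 1
    for layer, r in enumerate((radius, radius + 1.8)):
        for k in range(n_shell):
            zf = 1.0 - 2.0 * (k + 0.5) / n_shell
            rho = np.sqrt(max(0.0, 1.0 - zf * zf))
            ang = golden * k + layer * 0.3
            xyz = r * np.array([rho * np.cos(ang), rho * np.sin(ang), zf])
            lines.append(_format_atom(serial, "CA", "GLY", "B", resid, xyz, "C"))
            serial += 1
            resid += 1
    return "".join(lines) + "END\n"


# ---------------------------------------------------------------------------
# Synthetic deep-mutational-scanning training data
# ---------------------------------------------------------------------------

#: Generating coefficients of the synthetic DMS tables.  Chosen so that
#: (a) signs follow the biology — destabilizing structural scores and
#: conserved columns lower fitness, tolerated substitutions raise it —
#: and (b) the standardized weight of the evolutionary block is about
#: three times that of the structural block, the regime the model is
#: designed for.  Order: RSA, PoP, MAE, SNP, PVS, CI, LOR, PYF, intercept.
DEFAULT_TRUE_ALPHA = np.array(
    [0.002, -0.04, -0.05, -0.05, 0.04, -0.8, 0.045, 0.12, 0.9]
)

# per-feature (mean, sd) of the synthetic feature distributions
_FEATURE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "RSA": (40.0, 28.0),     # percent
    "PoP": (1.0, 1.0),       # predicted ddG, kcal/mol
    "MAE": (0.5, 0.8),       # predicted ddG, kcal/mol
    "SNP": (0.0, 1.0),       # deleteriousness score
    "PVS": (-2.5, 2.5),      # substitution-score delta
    "CI": (0.25, 0.12),      # Euclidean profile distance, >= 0
    "LOR": (-2.0, 2.0),      # logit difference
    "PYF": (-1.0, 1.0),      # statistical-energy difference
}


def make_synthetic_dms(
    n: int,
    seed: int,
    noise_sd: float = 0.1,
    true_alpha: np.ndarray | None = None,
    protein: str = "SYN1",
) -> tuple[TrainingSet, Coefficients]:
    """Generate a training table with exactly known coefficients.

    Features are drawn independently from the realistic per-feature
    ranges above (RSA clipped to be non-negative, CI truncated at
    zero); fitness is the linear combination under ``true_alpha`` plus
    Gaussian noise of sd ``noise_sd``.  Returns the table and the
    generating coefficients.
    """
    if true_alpha is None:
        true_alpha = DEFAULT_TRUE_ALPHA
    true_alpha = np.asarray(true_alpha, dtype=float)
    if true_alpha.shape != (9,):
        raise ValueError("true_alpha must have 9 entries")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)

    cols = {}
    for name, (mu, sd) in _FEATURE_DISTRIBUTIONS.items():
        x = rng.normal(mu, sd, size=n)
        if name in ("RSA", "CI"):
            x = np.abs(x)
        cols[name] = x
    X = np.column_stack([cols[f] for f in FEATURES])
    fitness = X @ true_alpha[:8] + true_alpha[8]
    if noise_sd > 0:
        fitness = fitness + rng.normal(0.0, noise_sd, size=n)

    positions = rng.integers(1, max(2, n // 19 + 2), size=n)
    wt_idx = rng.integers(0, 20, size=n)
    mt_shift = rng.integers(1, 20, size=n)
    mt_idx = (wt_idx + mt_shift) % 20
    table = pd.DataFrame({
        "protein": protein,
        "position": positions,
        "wt": [AMINO_ACIDS[i] for i in wt_idx],
        "mt": [AMINO_ACIDS[i] for i in mt_idx],
        **{f: cols[f] for f in FEATURES},
        "fitness": fitness,
    })
    # de-duplicate (protein, variant) keys by reassigning fresh positions
    key = table[["protein", "position", "wt", "mt"]].apply(tuple, axis=1)
    dup = key.duplicated()
    bump = 0
    while dup.any():
        table.loc[dup, "position"] = (
            table.loc[dup, "position"].to_numpy() + n // 19 + 1 + bump
        )
        key = table[["protein", "position", "wt", "mt"]].apply(tuple, axis=1)
        dup = key.duplicated()
        bump += n // 19 + 1
    truth = Coefficients(alpha=true_alpha, provenance=f"synthetic truth, seed={seed}")
    return TrainingSet(table=table), truth
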