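"""Structural features: solvent accessibility and external predictor tables.

Structures are read from PDB text.  Per-residue accessible surface area
is computed with Shrake–Rupley sphere quadrature over heavy atoms; all
chains in the file occlude each other, so multimeric context is taken
into account even though results are reported per chain.  Relative
solvent accessibility (RSA) normalizes the absolute ASA by the residue
type's ASA in an extended Gly-X-Gly tripeptide; values slightly above
100% can occur in unusual conformations and are deliberately not
clamped in the feature (clamping would inject a hidden nonlinearity
into a linear model).

The structural per-variant predictors themselves (stability-change and
deleteriousness scores named PoP, MAE and SNP downstream) are external
tools; this module only ingests their per-variant values from CSV
feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from Bio import Align

from .alignment_features import Variant, parse_variant
from .alphabet import THREE_TO_ONE

__all__ = [
    "Structure",
    "ResidueAccessibility",
    "ExternalFeatureTable",
    "StructureFormatError",
    "read_structure",
    "compute_sasa",
    "relative_solvent_accessibility",
    "load_max_asa",
    "load_feature_table",
    "PositionMap",
    "map_structure_to_sequence",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
FEATURE_COLUMNS = ("PoP", "MAE", "SNP")


class StructureFormatError(ValueError):
    """Raised when a PDB file cannot be parsed into a usable structure."""


@dataclass(frozen=True)
class Structure:
    """A parsed structure: heavy atoms only, waters removed.

    Wraps a biotite ``AtomArray`` (one altloc per atom, chosen by
    highest occupancy) and keeps the chain order of the file.
    """

    atoms: struc.AtomArray
    chains: tuple[str, ...]
    source: str = ""

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def chain_atoms(self, chain: str) -> struc.AtomArray:
        if chain not in self.chains:
            raise KeyError(
                f"chain {chain!r} not present; available chains: {list(self.chains)}"
            )
        return self.atoms[self.atoms.chain_id == chain]


def _check_coordinate_fields(text: str) -> None:
    """Validate coordinate fields of ATOM/HETATM records, with line numbers."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureFormatError(
                        f"malformed coordinate field {line[lo:hi]!r} on line {lineno}"
                    ) from None


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file, strip hydrogens and waters, resolve altlocs.

    Altloc groups are resolved by highest occupancy (ties go to the
    record appearing first, which in standard files is the
    lexicographically smallest altloc id).  All chains are retained.
    """
    path = Path(path)
    text = path.read_text()
    _check_coordinate_fields(text)
    pdb_file = PDBFile.read(str(path))
    try:
        atoms = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureFormatError(f"{path} contains no ATOM/HETATM records")
    keep = (atoms.element != "H") & (atoms.element != "D")
    keep &= ~np.isin(atoms.res_name, list(_WATER_NAMES))
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise StructureFormatError(
            f"{path} contains no heavy protein/ligand atoms after stripping "
            "hydrogens and waters"
        )
    if not np.all(np.isfinite(atoms.coord)):
        raise StructureFormatError(f"{path} contains non-finite coordinates")
    chains = tuple(dict.fromkeys(atoms.chain_id))
    return Structure(atoms=atoms, chains=chains, source=str(path))


@dataclass
class ResidueAccessibility:
    """Per-residue absolute ASA (Å²) and, once normalized, RSA (%).

    ``table`` columns: chain, res_id, ins_code, res_name, asa and —
    after :func:`relative_solvent_accessibility` — rsa.
    """

    table: pd.DataFrame

    def asa_of(self, chain: str, res_id: int, ins_code: str = "") -> float:
        return float(self._row(chain, res_id, ins_code)["asa"])

    def rsa_of(self, chain: str, res_id: int, ins_code: str = "") -> float:
        row = self._row(chain, res_id, ins_code)
        if "rsa" not in row or pd.isna(row.get("rsa", np.nan)):
            raise KeyError("RSA not computed yet; call relative_solvent_accessibility")
        return float(row["rsa"])

    def _row(self, chain, res_id, ins_code) -> pd.Series:
        t = self.table
        sel = (t["chain"] == chain) & (t["res_id"] == res_id) & (t["ins_code"] == ins_code)
        hits = t[sel]
        if hits.empty:
            raise KeyError(f"no residue {chain}/{res_id}{ins_code or ''}")
        return hits.iloc[0]


def compute_sasa(
    structure: Structure | struc.AtomArray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    vdw_radii: str | np.ndarray = "ProtOr",
) -> ResidueAccessibility:
    """Shrake–Rupley solvent-accessible surface area per residue.

    Each heavy atom is given a solvent-expanded sphere (van der Waals
    radius + probe radius, probe default 1.4 Å for water) sampled at
    ``n_points`` quadrature points; a point is accessible when no other
    expanded sphere covers it.  Per-residue ASA sums the residue's
    atoms.  Every chain present occludes every other, so complexes are
    handled as complexes.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("need at least 100 quadrature points per atom")
    atoms = structure.atoms if isinstance(structure, Structure) else structure
    atom_sasa = struc.sasa(
        atoms,
        probe_radius=probe_radius,
        point_number=n_points,
        vdw_radii=vdw_radii,
    )
    if not atoms.array_length():
        raise ValueError("empty structure")
    ins = (atoms.ins_code if "ins_code" in atoms.get_annotation_categories()
           else np.full(atoms.array_length(), ""))
    df = pd.DataFrame({
        "chain": atoms.chain_id,
        "res_id": atoms.res_id,
        "ins_code": ins,
        "res_name": atoms.res_name,
        "_asa": np.nan_to_num(atom_sasa, nan=0.0),
    })
    table = (
        df.groupby(["chain", "res_id", "ins_code", "res_name"], sort=False)["_asa"]
        .sum()
        .reset_index()
        .rename(columns={"_asa": "asa"})
    )
    return ResidueAccessibility(table=table)


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Load a per-residue-type maximum-ASA reference table.

    The bundled default holds extended Gly-X-Gly tripeptide values;
    a custom CSV with columns ``res_name,max_asa`` may be supplied.
    """
    if path is None:
        ref = resources.files("varfit.data") / "max_asa_glyxgly.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return dict(zip(df["res_name"].str.upper(), df["max_asa"].astype(float)))


def relative_solvent_accessibility(
    asa: ResidueAccessibility,
    reference: dict[str, float] | None = None,
) -> ResidueAccessibility:
    """Fill the RSA column: ``RSA(%) = 100 * ASA / max_asa(res type)``.

    Values above 100% are kept as-is; clamp only in reports, never in
    the feature itself.
    """
    if reference is None:
        reference = load_max_asa()
    table = asa.table.copy()
    unknown = sorted(set(table["res_name"].str.upper()) - set(reference))
    if unknown:
        raise KeyError(
            f"no reference max ASA for residue type(s): {', '.join(unknown)}"
        )
    ref = table["res_name"].str.upper().map(reference)
    table["rsa"] = 100.0 * table["asa"] / ref
    return ResidueAccessibility(table=table)


# ---------------------------------------------------------------------------
# External per-variant feature tables (PoP / MAE / SNP)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExternalFeatureTable:
    """Per-variant values of external structural predictors.

    ``table`` is indexed by (position, wt, mt); feature columns are
    float with NaN marking a genuinely absent value (never silently
    zero).
    """

    table: pd.DataFrame
    provenance: str = ""

    def get(self, variant: Variant, feature: str) -> float | None:
        """Value of ``feature`` for ``variant``, or None when absent."""
        key = (variant.position, variant.wt, variant.mt)
        if key not in self.table.index or feature not in self.table.columns:
            return None
        v = self.table.loc[key, feature]
        return None if pd.isna(v) else float(v)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.reset_index()
        out.insert(0, "variant", [
            f"{w}{p}{m}" for p, w, m in self.table.index
        ])
        out.drop(columns=["position", "wt", "mt"]).to_csv(path, index=False)


def load_feature_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    provenance: str = "",
) -> ExternalFeatureTable:
    """Read a CSV of external predictor scores keyed by variant.

    The variant key column may hold compact (``A123V``) or HGVS-style
    (``p.Ala123Val``) protein keys, or the table may carry separate
    ``position``/``wt``/``mt`` columns.  ``schema`` optionally maps the
    canonical names (``variant``, ``position``, ``wt``, ``mt``,
    ``PoP``, ``MAE``, ``SNP``) to the file's column names; by default a
    case-insensitive match on those names is used.  Missing cells stay
    missing; non-numeric cells and duplicate variants are errors.
    """
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    schema = schema or {}

    def col(name: str) -> str | None:
        if name in schema:
            return schema[name]
        return cols.get(name.lower())

    if col("variant"):
        variants = [parse_variant(v) for v in df[col("variant")]]
    elif col("position") and col("wt") and col("mt"):
        variants = [
            Variant(int(p), str(w).upper(), str(m).upper())
            for p, w, m in zip(df[col("position")], df[col("wt")], df[col("mt")])
        ]
    else:
        raise ValueError(
            f"{path}: need a 'variant' column or 'position'/'wt'/'mt' columns"
        )

    keys = [(v.position, v.wt, v.mt) for v in variants]
    dupes = pd.Index(keys)[pd.Index(keys).duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate variant keys: {list(dupes.unique())}")

    data: dict[str, list[float]] = {}
    for feat in FEATURE_COLUMNS:
        c = col(feat)
        if c is None or c not in df.columns:
            continue
        values = []
        for irow, cell in enumerate(df[c]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in column {c!r}, row {irow + 2}"
                ) from None
        data[feat] = values

    index = pd.MultiIndex.from_tuples(keys, names=["position", "wt", "mt"])
    table = pd.DataFrame(data, index=index, dtype=float)
    return ExternalFeatureTable(table=table, provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# Structure-to-sequence position mapping
# ---------------------------------------------------------------------------


def _chain_residues(structure: Structure, chain: str):
    """Ordered (res_id, ins_code, one_letter) triples of a chain's residues."""
    atoms = structure.chain_atoms(chain)
    ins = (atoms.ins_code if "ins_code" in atoms.get_annotation_categories()
           else np.full(atoms.array_length(), ""))
    seen = []
    seen_set = set()
    for rid, ic, rname in zip(atoms.res_id, ins, atoms.res_name):
        key = (int(rid), str(ic))
        if key not in seen_set:
            seen_set.add(key)
            seen.append((int(rid), str(ic), THREE_TO_ONE.get(rname.upper(), "X")))
    return seen


@dataclass(frozen=True)
class PositionMap:
    """Alignment of a structure chain to a query sequence.

    ``mapping`` sends 1-based query positions to ``(res_id, ins_code)``;
    ``unmapped`` holds query positions without a structural counterpart;
    ``mismatches`` records aligned pairs whose residue types disagree,
    as ``(query_position, query_residue, chain_residue)``.
    """

    mapping: dict[int, tuple[int, str]]
    unmapped: frozenset[int]
    mismatches: tuple[tuple[int, str, str], ...] = ()

    def __iter__(self):
        # allow `mapping, unmapped = map_structure_to_sequence(...)`
        return iter((self.mapping, set(self.unmapped)))


def map_structure_to_sequence(
    structure: Structure,
    chain: str,
    query: str,
) -> PositionMap:
    """Map 1-based query positions to structure residue ids of ``chain``.

    The chain's observed residue sequence is globally aligned to the
    query (high mismatch penalty, tolerant of gaps from unresolved
    loops), so author numbering offsets never leak into query
    coordinates.  Only exact residue matches anchor the map; aligned
    but disagreeing pairs are reported as mismatches.

    Fewer than half the query being mappable indicates the wrong chain
    or the wrong structure and is an error.
    """
    residues = _chain_residues(structure, chain)
    if not residues:
        raise KeyError(f"chain {chain!r} has no residues")
    chain_seq = "".join(r[2] for r in residues)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    # a substitution must stay cheaper than gapping around it on both
    # sides, otherwise real sequence disagreements hide as unmapped gaps
    aligner.mismatch_score = -10.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -0.5
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    alignment = aligner.align(query, chain_seq)[0]

    mapping: dict[int, tuple[int, str]] = {}
    mismatches: list[tuple[int, str, str]] = []
    for (q_start, q_end), (c_start, c_end) in zip(*alignment.aligned):
        for offset in range(q_end - q_start):
            qpos = q_start + offset + 1           # 1-based
            rid, ic, letter = residues[c_start + offset]
            if query[qpos - 1] == letter:          # only exact matches anchor
                mapping[qpos] = (rid, ic)
            else:
                mismatches.append((qpos, query[qpos - 1], letter))
    unmapped = frozenset(range(1, len(query) + 1)) - set(mapping)
    if len(mapping) < 0.5 * len(query):
        raise ValueError(
            f"only {len(mapping)}/{len(query)} query positions map to chain "
            f"{chain!r}; wrong chain or wrong structure?"
        )
    return PositionMap(
        mapping=mapping, unmapped=frozenset(unmapped), mismatches=tuple(mismatches)
    )
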