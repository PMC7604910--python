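"""Domain containers and file I/O for reflection and coordinate data.

A *multi-data set* is a collection of N paired crystallographic data sets
from one screening campaign: each entry couples a list of Miller-indexed
structure-factor amplitudes (``ReflectionSet``) with the refined atomic
model's C-alpha trace (``CoordinateModel``).

Reflections are read from MTZ files (via gemmi) or from a plain
tab-separated dialect with header ``h	k	l	F`` and an optional
``# cell a b c alpha beta gamma`` comment carrying the unit cell.
Coordinate models are read from PDB files; only C-alpha atoms are kept and,
where alternate conformations exist, only the first conformer encountered
in file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectionSet",
    "CoordinateModel",
    "MultiDataSet",
    "read_reflections",
    "read_model",
    "write_reflections_tsv",
    "write_reflections_mtz",
    "write_model_pdb",
    "write_partition",
]


def _validate_cell(cell: tuple[float, ...]) -> tuple[float, ...]:
    cell = tuple(float(x) for x in cell)
    if len(cell) != 6:
        raise ValueError("unit cell needs six values (a, b, c, alpha, beta, gamma)")
    if any(x <= 0 for x in cell[:3]):
        raise ValueError(f"unit-cell lengths must be positive, got {cell[:3]}")
    if any(not (0.0 < x < 180.0) for x in cell[3:]):
        raise ValueError(f"unit-cell angles must lie in (0, 180) degrees, got {cell[3:]}")
    return cell


@dataclass
class ReflectionSet:
    """One data set's Miller-indexed amplitudes plus its unit cell.

    Parameters
    ----------
    dataset_id : str
        Identifier unique within the multi-data set.
    hkl : (n, 3) int array
        Miller indices; triples must be unique within the set.
    f : (n,) float array
        Structure-factor amplitudes, finite and non-negative
        (arbitrary but consistent units).
    cell : 6-tuple
        a, b, c in Angstrom; alpha, beta, gamma in degrees.
    space_group : str, optional
        Hermann-Mauguin symbol, if known.
    """

    dataset_id: str
    hkl: np.ndarray
    f: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    space_group: str | None = None

    def __post_init__(self) -> None:
        self.hkl = np.ascontiguousarray(np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3))
        self.f = np.asarray(self.f, dtype=np.float64).reshape(-1)
        if len(self.hkl) != len(self.f):
            raise ValueError("hkl and f must have the same length")
        if not np.all(np.isfinite(self.f)) or np.any(self.f < 0):
            raise ValueError(f"{self.dataset_id}: amplitudes must be finite and >= 0")
        uniq, counts = np.unique(self.hkl, axis=0, return_counts=True)
        if len(uniq) != len(self.hkl):
            dup = uniq[counts > 1][0]
            raise ValueError(
                f"{self.dataset_id}: duplicate Miller index {tuple(int(x) for x in dup)}"
            )
        self.cell = _validate_cell(self.cell)

    def __len__(self) -> int:
        return len(self.f)

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def reciprocal_radii(self) -> np.ndarray:
        """|s| = 1/d per reflection (A^-1), from this set's own unit cell."""
        return reciprocal_radius(self.cell, self.hkl)

    def d_spacings(self) -> np.ndarray:
        return 1.0 / self.reciprocal_radii()

    def replace(self, **kw) -> "ReflectionSet":
        args = dict(
            dataset_id=self.dataset_id,
            hkl=self.hkl,
            f=self.f,
            cell=self.cell,
            space_group=self.space_group,
        )
        args.update(kw)
        return ReflectionSet(**args)


def reciprocal_radius(cell: tuple[float, ...], hkl: np.ndarray) -> np.ndarray:
    """Reciprocal-space radius |s| = 1/d for Miller indices in a given cell.

    Uses the reciprocal metric tensor G* (inverse of the direct metric), so
    it is valid for any crystal system: 1/d^2 = h G* h^T.
    """
    a, b, c, al, be, ga = _validate_cell(cell)
    ca, cb, cg = (np.cos(np.radians(x)) for x in (al, be, ga))
    g = np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )
    gstar = np.linalg.inv(g)
    h = np.asarray(hkl, dtype=np.float64).reshape(-1, 3)
    s2 = np.einsum("ij,jk,ik->i", h, gstar, h)
    return np.sqrt(s2)


@dataclass
class CoordinateModel:
    """One data set's ordered C-alpha trace.

    ``atom_keys`` are "chain/resseq/icode" strings, unique per model (one
    C-alpha per residue after first-conformer filtering); ``coords`` are
    orthogonal-frame positions in Angstrom.
    """

    dataset_id: str
    atom_keys: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.atom_keys = list(self.atom_keys)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if len(self.atom_keys) != len(self.coords):
            raise ValueError("atom_keys and coords must have the same length")
        if len(set(self.atom_keys)) != len(self.atom_keys):
            raise ValueError(f"{self.dataset_id}: duplicate atom keys")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.dataset_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atom_keys)

    def replace(self, **kw) -> "CoordinateModel":
        args = dict(dataset_id=self.dataset_id, atom_keys=self.atom_keys, coords=self.coords)
        args.update(kw)
        return CoordinateModel(**args)


@dataclass
class MultiDataSet:
    """N paired (ReflectionSet, CoordinateModel) entries with unique ids."""

    entries: list[tuple[ReflectionSet, CoordinateModel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rs.dataset_id for rs, _ in self.entries]
        for rs, cm in self.entries:
            if rs.dataset_id != cm.dataset_id:
                raise ValueError(f"pair mismatch: {rs.dataset_id} vs {cm.dataset_id}")
        if len(set(ids)) != len(ids):
            raise ValueError("dataset_id values must be unique across entries")

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def dataset_ids(self) -> list[str]:
        return [rs.dataset_id for rs, _ in self.entries]

    @property
    def reflection_sets(self) -> list[ReflectionSet]:
        return [rs for rs, _ in self.entries]

    @property
    def models(self) -> list[CoordinateModel]:
        return [cm for _, cm in self.entries]

    def subset(self, dataset_ids) -> "MultiDataSet":
        wanted = set(dataset_ids)
        return MultiDataSet([e for e in self.entries if e[0].dataset_id in wanted])


# ---------------------------------------------------------------------------
# readers


def read_reflections(
    path: str | Path,
    format: str | None = None,
    dataset_id: str | None = None,
    column: str | None = None,
    cell: tuple[float, ...] | None = None,
) -> ReflectionSet:
    """Read a reflection list from an MTZ file or the TSV dialect.

    Parameters
    ----------
    format : {"mtz", "tsv"}, optional
        Inferred from the file suffix when omitted.
    column : str, optional
        MTZ amplitude column label; defaults to the first F-typed column.
    cell : 6-tuple, optional
        Overrides/provides the unit cell for TSV files lacking a
        ``# cell`` comment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtz" if path.suffix.lower() == ".mtz" else "tsv"
    if dataset_id is None:
        dataset_id = path.stem
    if format == "mtz":
        return _read_mtz(path, dataset_id, column)
    if format == "tsv":
        return _read_tsv(path, dataset_id, cell)
    raise ValueError(f"unknown reflection format {format!r}")


def _read_mtz(path: Path, dataset_id: str, column: str | None) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    if column is None:
        fcols = [c for c in mtz.columns if c.type == "F"]
        if not fcols:
            available = ", ".join(f"{c.label}({c.type})" for c in mtz.columns)
            raise ValueError(
                f"{path}: no amplitude (type F) column; available columns: {available}"
            )
        col = fcols[0]
    else:
        col = mtz.column_with_label(column)
        if col is None:
            available = ", ".join(c.label for c in mtz.columns)
            raise ValueError(f"{path}: no column {column!r}; available: {available}")
    arr = np.array(mtz, copy=True)
    hkl = arr[:, :3].astype(np.int64)
    f = arr[:, col.idx]
    keep = np.isfinite(f)
    cell = mtz.cell
    sg = mtz.spacegroup.hm if mtz.spacegroup else None
    return ReflectionSet(
        dataset_id,
        hkl[keep],
        f[keep],
        (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        space_group=sg,
    )


def _read_tsv(path: Path, dataset_id: str, cell: tuple[float, ...] | None) -> ReflectionSet:
    hkl: list[tuple[int, int, int]] = []
    f: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "cell":
                    cell = tuple(float(x) for x in parts[1:7])
                continue
            fields = line.split("\t")
            if not header_seen:
                if [x.strip() for x in fields[:4]] != ["h", "k", "l", "F"]:
                    raise ValueError(f"{path}:{lineno}: expected header 'h\\tk\\tl\\tF'")
                header_seen = True
                continue
            try:
                h, k, l = (int(x) for x in fields[:3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer Miller index") from exc
            hkl.append((h, k, l))
            f.append(float(fields[3]))
    if cell is None:
        raise ValueError(f"{path}: no unit cell ('# cell a b c alpha beta gamma' line missing)")
    return ReflectionSet(dataset_id, np.array(hkl, dtype=np.int64).reshape(-1, 3),
                         np.array(f), cell)


def read_model(path: str | Path, dataset_id: str | None = None) -> CoordinateModel:
    """Read a PDB file, keeping one C-alpha per residue.

    For residues with alternate locations the first C-alpha record in file
    order wins, regardless of altloc label.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    keys: list[str] = []
    coords: list[tuple[float, float, float]] = []
    seen: set[str] = set()
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.name != "CA" or atom.element != gemmi.Element("C"):
                    continue
                icode = residue.seqid.icode.strip()
                key = f"{chain.name}/{residue.seqid.num}/{icode}"
                if key in seen:  # later conformer or duplicate record
                    continue
                seen.add(key)
                keys.append(key)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not keys:
        raise ValueError(f"{path}: no C-alpha atoms found")
    return CoordinateModel(dataset_id, keys, np.array(coords))


# ---------------------------------------------------------------------------
# writers


def write_reflections_tsv(rs: ReflectionSet, path: str | Path) -> None:
    """Write the TSV dialect: cell comment, 'h k l F' header, one row per reflection."""
    path = Path(path)
    a, b, c, al, be, ga = rs.cell
    with open(path, "w") as fh:
        fh.write(f"# cell {a:.6f} {b:.6f} {c:.6f} {al:.6f} {be:.6f} {ga:.6f}\n")
        fh.write("h\tk\tl\tF\n")
        for (h, k, l), f in zip(rs.hkl, rs.f):
            fh.write(f"{h}\t{k}\t{l}\t{f:.8g}\n")


def write_reflections_mtz(rs: ReflectionSet, path: str | Path) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(rs.space_group or "P 1")
    mtz.set_cell_for_all(gemmi.UnitCell(*rs.cell))
    mtz.add_dataset("data")
    mtz.add_column("F", "F")
    data = np.column_stack([rs.hkl.astype(np.float64), rs.f])
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def write_model_pdb(cm: CoordinateModel, path: str | Path, cell=None) -> None:
    """Write a minimal PDB with one CA record per atom key."""
    st = gemmi.Structure()
    st.name = cm.dataset_id
    if cell is not None:
        st.cell = gemmi.UnitCell(*cell)
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for key, xyz in zip(cm.atom_keys, cm.coords):
        chain_name, resseq, icode = key.split("/")
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(resseq), icode if icode else " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chains[chain_name].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_partition(tree, out_dir: str | Path) -> list[Path]:
    """Write one id list per terminal cluster, an assignment table and the tree.

    Outputs, all deterministically ordered:

    - ``<leaf-id>.txt`` — member dataset_ids, one per line, sorted;
    - ``assignment.tsv`` — columns dataset_id, cluster_path;
    - ``tree.yaml`` — the full cluster tree with per-node provenance.

    Raises if a dataset_id appears in more than one terminal cluster.
    """
    from .cluster import ClusterNode  # local import to avoid a cycle

    assert isinstance(tree, ClusterNode)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaves = tree.leaves()
    assigned: dict[str, str] = {}
    for leaf in leaves:
        for did in leaf.members:
            if did in assigned:
                raise ValueError(
                    f"dataset {did!r} assigned to both {assigned[did]!r} and {leaf.id!r}"
                )
            assigned[did] = leaf.id
    written: list[Path] = []
    for leaf in leaves:
        if not leaf.members:
            logger.warning("terminal cluster %s is empty; file omitted", leaf.id)
            continue
        p = out_dir / f"{leaf.id}.txt"
        p.write_text("".join(f"{did}\n" for did in sorted(leaf.members)))
        written.append(p)
    table = out_dir / "assignment.tsv"
    with open(table, "w") as fh:
        fh.write("dataset_id\tcluster_path\n")
        for did in sorted(assigned):
            fh.write(f"{did}\t{assigned[did]}\n")
    written.append(table)
    tree_path = out_dir / "tree.yaml"
    with open(tree_path, "w") as fh:
        yaml.safe_dump(tree.to_dict(), fh, sort_keys=False)
    written.append(tree_path)
    return written
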