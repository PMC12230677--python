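"""Versioned exchange-file I/O for stockholder partitions.

Two dialects are supported:

``qdr-json``
    One JSON document with a ``format``/``version`` header, a ``cell``
    block, an ``atoms`` table, and a ``pairs`` table.

``qdr-csv``
    One plain-text file with a ``#QDR-CSV v1`` header and three sections
    (``[cell]``, ``[atoms]``, ``[pairs]``), each a small CSV table.

Coordinates and cutoff radii are in angstrom on file; dipoles (e*bohr) and
quadrupoles (e*bohr^2) are in atomic units, matching how such quantities
are normally tabulated.  Pairs may be listed in one direction only; the
mirrored direction is synthesized on load.  Mirrored duplicates with
conflicting overlap populations are rejected.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, SYMBOL_TO_NUMBER
from .errors import SchemaError
from .partition import AtomSite, Cell, PairSet, StockholderPartition

logger = logging.getLogger(__name__)

FORMAT_NAME = "qdr-partition"
FORMAT_VERSION = 1


def _complete_mirrors(pair_rows: list[dict]) -> list[dict]:
    """Ensure both directions of every pair are present, checking clashes."""
    table: dict[tuple, float] = {}
    for row in pair_rows:
        tr = tuple(int(t) for t in row["translation"])
        key = (int(row["atom_a"]), int(row["atom_b"]), tr)
        op = float(row["op"])
        for k in (key, (key[1], key[0], tuple(-t for t in tr))):
            if k in table and abs(table[k] - op) > 1e-12:
                raise SchemaError(
                    f"pair {key}: mirrored duplicate with conflicting op "
                    f"{table[k]} vs {op}"
                )
        table[key] = op
        mk = (key[1], key[0], tuple(-t for t in tr))
        table.setdefault(mk, op)
    return [
        {"atom_a": a, "atom_b": b, "translation": list(tr), "op": op}
        for (a, b, tr), op in sorted(table.items())
    ]


def _pairs_from_rows(rows: list[dict], atoms: list[AtomSite], cell: Cell) -> PairSet:
    pos = np.array([a.position for a in atoms])
    n = len(rows)
    atom_a = np.zeros(n, dtype=int)
    atom_b = np.zeros(n, dtype=int)
    translation = np.zeros((n, 3), dtype=int)
    op = np.zeros(n)
    dist = np.zeros(n)
    dirs = np.zeros((n, 3))
    for i, row in enumerate(rows):
        a, b = int(row["atom_a"]), int(row["atom_b"])
        if not (0 <= a < len(atoms) and 0 <= b < len(atoms)):
            raise SchemaError(f"pair record {i}: atom index out of range: {row}")
        tr = np.asarray(row["translation"], dtype=int)
        disp = pos[b] + tr.astype(float) @ cell.lattice - pos[a]
        d = float(np.linalg.norm(disp))
        if d == 0.0:
            raise SchemaError(f"pair record {i}: zero-distance self pair: {row}")
        atom_a[i], atom_b[i] = a, b
        translation[i] = tr
        op[i] = float(row["op"])
        dist[i] = d
        dirs[i] = disp / d
    ps = PairSet(atom_a, atom_b, translation, op, dist, dirs)
    ps.build_index(len(atoms))
    return ps


def _partition_from_dict(doc: dict) -> StockholderPartition:
    if doc.get("format") != FORMAT_NAME:
        raise SchemaError(f"not a {FORMAT_NAME} document (format={doc.get('format')!r})")
    if int(doc.get("version", -1)) != FORMAT_VERSION:
        raise SchemaError(f"unsupported schema version {doc.get('version')!r}")

    cell_doc = doc.get("cell") or {}
    lattice_ang = np.asarray(cell_doc.get("lattice", np.zeros((3, 3))), dtype=float)
    cell = Cell(
        lattice=lattice_ang * ANGSTROM_TO_BOHR,
        periodic_flags=tuple(cell_doc.get("periodic", (False, False, False))),
    )

    atoms = []
    for i, row in enumerate(doc.get("atoms", [])):
        try:
            elem = row["element"]
            if isinstance(elem, str):
                elem = SYMBOL_TO_NUMBER[elem]
            atoms.append(
                AtomSite(
                    index=i,
                    element=int(elem),
                    position=np.asarray(row["position"], dtype=float) * ANGSTROM_TO_BOHR,
                    charge=float(row.get("charge", 0.0)),
                    dipole=np.asarray(row.get("dipole", np.zeros(3)), dtype=float),
                    quadrupole=np.asarray(
                        row.get("quadrupole", np.zeros((3, 3))), dtype=float
                    ),
                    n_electrons=(
                        float(row["n_electrons"]) if row.get("n_electrons") is not None else None
                    ),
                    cloud_a=(float(row["cloud_a"]) if row.get("cloud_a") is not None else None),
                    cloud_b=(float(row["cloud_b"]) if row.get("cloud_b") is not None else None),
                    cutoff_radius=float(row.get("cutoff_radius", 5.0)) * ANGSTROM_TO_BOHR,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed atom record {i}: {row!r} ({exc})") from exc

    pair_rows = []
    for i, row in enumerate(doc.get("pairs", [])):
        try:
            pair_rows.append(
                {
                    "atom_a": int(row["atom_a"]),
                    "atom_b": int(row["atom_b"]),
                    "translation": list(row.get("translation", (0, 0, 0))),
                    "op": float(row["op"]),
                }
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed pair record {i}: {row!r} ({exc})") from exc

    pairs = _pairs_from_rows(_complete_mirrors(pair_rows), atoms, cell)
    part = StockholderPartition(
        atoms=atoms,
        cell=cell,
        pairs=pairs,
        method_name=str(doc.get("method_name", "")),
        net_charge=float(doc.get("net_charge", 0.0)),
    )
    part.validate()
    return part


def _partition_to_dict(part: StockholderPartition) -> dict:
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "method_name": part.method_name,
        "net_charge": part.net_charge,
        "cell": {
            "lattice": (part.cell.lattice * BOHR_TO_ANGSTROM).tolist(),
            "periodic": list(part.cell.periodic_flags),
        },
        "atoms": [
            {
                "element": a.element,
                "position": (a.position * BOHR_TO_ANGSTROM).tolist(),
                "charge": a.charge,
                "dipole": a.dipole.tolist(),
                "quadrupole": a.quadrupole.tolist(),
                "n_electrons": a.n_electrons,
                "cloud_a": a.cloud_a,
                "cloud_b": a.cloud_b,
                "cutoff_radius": a.cutoff_radius * BOHR_TO_ANGSTROM,
            }
            for a in part.atoms
        ],
        "pairs": [],
    }
    if part.pairs is not None:
        for p in range(len(part.pairs)):
            doc["pairs"].append(
                {
                    "atom_a": int(part.pairs.atom_a[p]),
                    "atom_b": int(part.pairs.atom_b[p]),
                    "translation": part.pairs.translation[p].tolist(),
                    "op": float(part.pairs.op[p]),
                }
            )
    return doc


# ---------------------------------------------------------------------------
# qdr-csv dialect
# ---------------------------------------------------------------------------

_ATOM_COLUMNS = (
    "element,x,y,z,charge,dipole_x,dipole_y,dipole_z,"
    "q_xx,q_xy,q_xz,q_yy,q_yz,q_zz,n_electrons,cloud_a,cloud_b,cutoff_radius"
)
_PAIR_COLUMNS = "atom_a,atom_b,l1,l2,l3,op"


def _write_csv(part: StockholderPartition, path: Path) -> None:
    doc = _partition_to_dict(part)
    lines = [f"#QDR-CSV v{FORMAT_VERSION}"]
    lines.append(f"#method_name,{doc['method_name']}")
    lines.append(f"#net_charge,{doc['net_charge']!r}")
    lines.append("[cell]")
    lines.append("periodic," + ",".join(str(int(f)) for f in doc["cell"]["periodic"]))
    for row in doc["cell"]["lattice"]:
        lines.append("lattice," + ",".join(repr(v) for v in row))
    lines.append("[atoms]")
    lines.append(_ATOM_COLUMNS)
    for a in doc["atoms"]:
        q = a["quadrupole"]
        vals = (
            [a["element"], *a["position"], a["charge"], *a["dipole"],
             q[0][0], q[0][1], q[0][2], q[1][1], q[1][2], q[2][2],
             a["n_electrons"], a["cloud_a"], a["cloud_b"], a["cutoff_radius"]]
        )
        lines.append(",".join("" if v is None else repr(v) for v in vals))
    lines.append("[pairs]")
    lines.append(_PAIR_COLUMNS)
    for p in doc["pairs"]:
        lines.append(
            ",".join(
                repr(v) if isinstance(v, float) else str(v)
                for v in (p["atom_a"], p["atom_b"], *p["translation"], p["op"])
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _read_csv(path: Path) -> dict:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    if not lines or not lines[0].startswith("#QDR-CSV v"):
        raise SchemaError(f"{path}: missing #QDR-CSV version header")
    if lines[0] != f"#QDR-CSV v{FORMAT_VERSION}":
        raise SchemaError(f"{path}: unsupported version header {lines[0]!r}")
    doc: dict = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "method_name": "",
        "net_charge": 0.0,
        "cell": {"lattice": [[0.0] * 3 for _ in range(3)], "periodic": [False] * 3},
        "atoms": [],
        "pairs": [],
    }
    section = None
    lattice_rows: list[list[float]] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        if ln.startswith("#method_name,"):
            doc["method_name"] = ln.split(",", 1)[1]
            continue
        if ln.startswith("#net_charge,"):
            doc["net_charge"] = float(ln.split(",", 1)[1])
            continue
        if ln.startswith("["):
            section = ln.strip()
            continue
        cells = ln.split(",")
        try:
            if section == "[cell]":
                if cells[0] == "periodic":
                    doc["cell"]["periodic"] = [bool(int(v)) for v in cells[1:4]]
                elif cells[0] == "lattice":
                    lattice_rows.append([float(v) for v in cells[1:4]])
            elif section == "[atoms]":
                if ln == _ATOM_COLUMNS:
                    continue
                v = [None if c == "" else float(c) for c in cells]
                doc["atoms"].append(
                    {
                        "element": int(v[0]),
                        "position": v[1:4],
                        "charge": v[4],
                        "dipole": v[5:8],
                        "quadrupole": [
                            [v[8], v[9], v[10]],
                            [v[9], v[11], v[12]],
                            [v[10], v[12], v[13]],
                        ],
                        "n_electrons": v[14],
                        "cloud_a": v[15],
                        "cloud_b": v[16],
                        "cutoff_radius": v[17] if v[17] is not None else 5.0,
                    }
                )
            elif section == "[pairs]":
                if ln == _PAIR_COLUMNS:
                    continue
                doc["pairs"].append(
                    {
                        "atom_a": int(cells[0]),
                        "atom_b": int(cells[1]),
                        "translation": [int(cells[2]), int(cells[3]), int(cells[4])],
                        "op": float(cells[5]),
                    }
                )
        except (ValueError, IndexError) as exc:
            raise SchemaError(f"{path}:{ln_no}: malformed record {ln!r} ({exc})") from exc
    if lattice_rows:
        doc["cell"]["lattice"] = lattice_rows
    return doc


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def load_partition(path, dialect: str | None = None) -> StockholderPartition:
    """Load a stockholder partition from a ``qdr-json`` or ``qdr-csv`` file.

    ``dialect`` is inferred from the file suffix when omitted (.json /
    .csv).  All partition invariants are checked; positions are converted
    angstrom -> bohr; missing mirrored pairs are synthesized.
    """
    path = Path(path)
    if dialect is None:
        dialect = "qdr-json" if path.suffix.lower() == ".json" else "qdr-csv"
    logger.debug("loading partition from %s (dialect=%s)", path, dialect)
    if dialect == "qdr-json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    elif dialect == "qdr-csv":
        doc = _read_csv(path)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")
    return _partition_from_dict(doc)


def save_partition(part: StockholderPartition, path, dialect: str | None = None) -> None:
    """Write a partition to disk in the requested dialect."""
    path = Path(path)
    if dialect is None:
        dialect = "qdr-json" if path.suffix.lower() == ".json" else "qdr-csv"
    logger.debug("saving partition to %s (dialect=%s)", path, dialect)
    if dialect == "qdr-json":
        path.write_text(json.dumps(_partition_to_dict(part), indent=1))
    elif dialect == "qdr-csv":
        _write_csv(part, path)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")


def read_xyz(path) -> StockholderPartition:
    """Read a bare XYZ geometry into a partition with zero charges/moments."""
    lines = Path(path).read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise SchemaError(f"{path}: not an XYZ file ({exc})") from exc
    atoms = []
    for i, ln in enumerate(lines[2 : 2 + n]):
        parts = ln.split()
        sym = parts[0]
        elem = int(sym) if sym.isdigit() else SYMBOL_TO_NUMBER.get(sym.capitalize())
        if elem is None:
            raise SchemaError(f"{path}: unknown element {sym!r} on line {i + 3}")
        pos = np.array([float(v) for v in parts[1:4]]) * ANGSTROM_TO_BOHR
        atoms.append(AtomSite(index=i, element=elem, position=pos))
    return StockholderPartition(atoms=atoms)
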