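"""Particle data model and file I/O.

The substrate of every membrane metric is an ensemble of labelled particles:
each particle carries a species (which molecule type it belongs to), a role
(which chemical moiety it represents — phosphate, glycerol backbone, acyl
tail carbon, water oxygen, alcohol hydroxyl/terminal methyl, tail hydrogen)
and, for chain atoms, a chain id and carbon index.  Coordinates are in nm
with the membrane normal along z and the bilayer midplane at z = 0.

Two on-disk formats are supported:

* a *labelled particle table*: a UTF-8 TSV with header
  ``frame mol_id species role chain_id carbon_index x y z`` plus a sidecar
  JSON (``<path>.meta.json``) holding per-frame box dimensions and free-form
  metadata;
* multi-frame concatenated GRO coordinate files, with species/role
  assignment driven by an external :class:`RoleMap` (force-field naming
  varies, so the mapping is configuration, not code).

Internally an ensemble is a single :class:`pandas.DataFrame` with a
``frame`` column plus an ``(n_frames, 3)`` array of box dimensions; this is
the natural container for the vectorised histogram and group-by operations
the metrics are built on.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError

SPECIES = (
    "DOPC",
    "POPI",
    "IPC",
    "ERG",
    "WATER",
    "ETHANOL",
    "BUTANOL",
    "ION",
    "OTHER",
)

ROLES = (
    "phosphate",
    "glycerol_backbone",
    "tail_carbon",
    "water_oxygen",
    "hydroxyl_oxygen",
    "terminal_methyl",
    "tail_hydrogen",
    "other",
)

#: Column order of the labelled particle table.
TABLE_COLUMNS = (
    "frame",
    "mol_id",
    "species",
    "role",
    "chain_id",
    "carbon_index",
    "x",
    "y",
    "z",
)

#: Control membrane composition: 44 DOPC + 44 POPI (35% each) and
#: 20 IPC + 20 ergosterol (15% each), 128 lipids in total.
CONTROL_COMPOSITION = {"DOPC": 44, "POPI": 44, "IPC": 20, "ERG": 20}


@dataclass(frozen=True)
class Particle:
    """A single labelled particle (convenience view, not the storage)."""

    particle_id: int
    molecule_id: int
    species: str
    role: str
    chain_id: int
    carbon_index: int
    position: tuple[float, float, float]


@dataclass
class ParticleFrame:
    """One frame of an ensemble: a box and a particle table slice."""

    frame_index: int
    box: np.ndarray  # (Lx, Ly, Lz) in nm
    particles: pd.DataFrame


@dataclass
class ParticleEnsemble:
    """Frames of labelled particles with per-frame box dimensions.

    ``table`` has the columns of :data:`TABLE_COLUMNS`; rows are ordered by
    frame and, within a frame, by particle id.  ``boxes[i]`` is the
    ``(Lx, Ly, Lz)`` box of frame ``i``.  ``metadata`` is free-form (alcohol
    species, nominal concentration, lipid counts, generator truth records);
    estimators never read it except for explicitly documented keys.
    """

    table: pd.DataFrame
    boxes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.boxes.ndim != 2 or self.boxes.shape[1] != 3:
            raise ParseError("boxes must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.boxes)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.arange(self.n_frames)

    def frame(self, i: int) -> ParticleFrame:
        sub = self.table[self.table["frame"] == i]
        return ParticleFrame(i, self.boxes[i], sub)

    def select(self, sel) -> pd.DataFrame:
        """Return the sub-table matched by a selection.

        ``sel`` is either a callable on the table returning a boolean mask,
        or a mapping column -> value (or list of values).
        """
        if callable(sel):
            return self.table[sel(self.table)]
        mask = np.ones(len(self.table), dtype=bool)
        for col, val in sel.items():
            colv = self.table[col]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= colv.isin(list(val)).to_numpy()
            else:
                mask &= (colv == val).to_numpy()
        return self.table[mask]

    def resample_frames(self, indices) -> "ParticleEnsemble":
        """Build a new ensemble from frames ``indices`` (with repetition)."""
        indices = np.asarray(indices, dtype=int)
        parts = []
        for new_idx, old_idx in enumerate(indices):
            sub = self.table[self.table["frame"] == old_idx].copy()
            sub["frame"] = new_idx
            parts.append(sub)
        table = pd.concat(parts, ignore_index=True)
        meta = dict(self.metadata)
        return ParticleEnsemble(table, self.boxes[indices], meta)

    def validate(self) -> None:
        """Check every data-model invariant; raise ParseError on violation."""
        missing = [c for c in TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParseError(f"missing column(s): {', '.join(missing)}")
        if self.n_frames < 1:
            raise ParseError("ensemble must contain at least one frame")
        if not np.all(self.boxes > 0):
            raise ParseError("box components must be positive")
        bad_species = set(self.table["species"].unique()) - set(SPECIES)
        if bad_species:
            raise ParseError(f"unknown species token(s): {sorted(bad_species)}")
        bad_roles = set(self.table["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ParseError(f"unknown role token(s): {sorted(bad_roles)}")
        counts = self.table.groupby("frame").size()
        frames_seen = set(counts.index)
        if frames_seen != set(range(self.n_frames)):
            raise ParseError("frame indices must be 0..n_frames-1 and match boxes")
        if counts.nunique() != 1:
            raise ParseError("inconsistent particle count across frames")
        xyz = self.table[["x", "y", "z"]].to_numpy()
        if not np.all(np.isfinite(xyz)):
            raise ParseError("non-finite coordinate")
        tail = self.table[self.table["role"] == "tail_carbon"]
        if len(tail) and (tail["carbon_index"] < 1).any():
            raise ParseError("tail_carbon particles must have carbon_index >= 1")
        alc_roles = self.table["role"].isin(["hydroxyl_oxygen", "terminal_methyl"])
        alc = self.table[alc_roles]
        if len(alc) and (~alc["species"].isin(["ETHANOL", "BUTANOL"])).any():
            raise ParseError(
                "hydroxyl_oxygen/terminal_methyl roles occur only on alcohols"
            )


# ---------------------------------------------------------------------------
# Role mapping (GRO residue/atom names -> species/role labels)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoleRule:
    residue: str
    atom: str
    species: str
    role: str
    chain_id: int = 0
    carbon_index: int = 0


@dataclass
class RoleMap:
    """Ordered shell-glob rules mapping (residue, atom) names to labels.

    The first matching rule wins; names matched by no rule are kept with
    species OTHER / role other so the reader never silently drops atoms.
    """

    rules: list[RoleRule]

    def lookup(self, residue: str, atom: str) -> tuple[str, str, int, int]:
        for r in self.rules:
            if fnmatch.fnmatchcase(residue, r.residue) and fnmatch.fnmatchcase(
                atom, r.atom
            ):
                return (r.species, r.role, r.chain_id, r.carbon_index)
        return ("OTHER", "other", 0, 0)

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        rules = []
        for entry in doc["rules"]:
            species = entry["species"]
            role = entry["role"]
            if species not in SPECIES:
                raise ParseError(f"unknown species token: {species}")
            if role not in ROLES:
                raise ParseError(f"unknown role token: {role}")
            rules.append(
                RoleRule(
                    residue=str(entry["residue"]),
                    atom=str(entry["atom"]),
                    species=species,
                    role=role,
                    chain_id=int(entry.get("chain_id", 0)),
                    carbon_index=int(entry.get("carbon_index", 0)),
                )
            )
        return cls(rules)

    def to_yaml(self, path) -> None:
        doc = {
            "rules": [
                {
                    "residue": r.residue,
                    "atom": r.atom,
                    "species": r.species,
                    "role": r.role,
                    "chain_id": r.chain_id,
                    "carbon_index": r.carbon_index,
                }
                for r in self.rules
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# Canonical GRO naming used by the package's own writer.
_RESNAME = {
    "DOPC": "DOPC",
    "POPI": "POPI",
    "IPC": "IPC",
    "ERG": "ERG",
    "WATER": "SOL",
    "ETHANOL": "ETOH",
    "BUTANOL": "BUOH",
    "ION": "ION",
    "OTHER": "UNK",
}
_RESNAME_INV = {v: k for k, v in _RESNAME.items()}

_PLAIN_ATOM = {
    "phosphate": "P",
    "glycerol_backbone": "GL",
    "water_oxygen": "OW",
    "hydroxyl_oxygen": "OH",
    "terminal_methyl": "CT",
    "other": "X",
}


def _atom_name(role: str, chain_id: int, carbon_index: int) -> str:
    if role == "tail_carbon":
        return f"C{chain_id}{carbon_index:02d}"
    if role == "tail_hydrogen":
        return f"H{chain_id}{carbon_index:02d}"
    return _PLAIN_ATOM[role]


def canonical_role_map(max_carbons: int = 30, chains=(1, 2)) -> RoleMap:
    """RoleMap matching the atom names emitted by :func:`write_gro_frames`."""
    rules = []
    for species, res in _RESNAME.items():
        if species == "OTHER":
            continue
        for role, atom in _PLAIN_ATOM.items():
            rules.append(RoleRule(res, atom, species, role))
        for c in chains:
            for i in range(1, max_carbons + 1):
                rules.append(RoleRule(res, f"C{c}{i:02d}", species, "tail_carbon", c, i))
                rules.append(
                    RoleRule(res, f"H{c}{i:02d}", species, "tail_hydrogen", c, i)
                )
    return RoleMap(rules)


# ---------------------------------------------------------------------------
# Labelled particle table I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_particle_table(ens: ParticleEnsemble, path) -> None:
    """Write a labelled particle table plus its box/metadata sidecar JSON."""
    ens.validate()
    df = ens.table[list(TABLE_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "boxes": [[float(v) for v in row] for row in ens.boxes],
        "metadata": ens.metadata,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)


def read_particle_table(path) -> ParticleEnsemble:
    """Read a labelled particle table (TSV, gzip allowed) with sidecar JSON."""
    try:
        df = pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ParseError(f"cannot parse particle table {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}")
    side = _sidecar_path(path)
    if not side.exists():
        raise ParseError(f"missing sidecar metadata file: {side}")
    with open(side, "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    boxes = np.asarray(sidecar["boxes"], dtype=float)
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    # Normalise frame labels to 0..n-1 preserving order.
    uniq = np.sort(df["frame"].unique())
    if len(uniq) != len(boxes):
        raise ParseError(
            f"table has {len(uniq)} frames but sidecar lists {len(boxes)} boxes"
        )
    df["frame"] = df["frame"].map({u: i for i, u in enumerate(uniq)})
    ens = ParticleEnsemble(df, boxes, dict(sidecar.get("metadata", {})))
    ens.validate()
    return ens


# ---------------------------------------------------------------------------
# GRO I/O
# ---------------------------------------------------------------------------


def read_gro_frames(path, role_map: RoleMap, recenter: bool = True) -> ParticleEnsemble:
    """Read a (possibly multi-frame, concatenated) GRO coordinate file.

    Positions are nm (GRO native).  Species/role labels come from
    ``role_map``; unmatched atoms are kept as OTHER/other and tallied in
    ``metadata['n_unmapped']``.  When ``recenter`` is true each frame is
    shifted so the phosphate centre of mass sits at z = 0 (the membrane
    metrics are all defined relative to the bilayer midplane, and a
    pressure-coupled box drifts), and coordinates are wrapped into the box.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    frames = []
    boxes = []
    pos = 0
    lookup_cache: dict[tuple[str, str], tuple[str, str, int, int]] = {}
    n_unmapped = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise ParseError("truncated GRO file: missing atom count line")
        try:
            natoms = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise ParseError(
                f"bad atom count line at line {pos + 2}: {lines[pos + 1]!r}"
            ) from exc
        atom_lines = lines[pos + 2 : pos + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ParseError("GRO atom count disagrees with number of atom rows")
        box_line_idx = pos + 2 + natoms
        if box_line_idx >= len(lines):
            raise ParseError("truncated GRO file: missing box line")
        box_fields = lines[box_line_idx].split()
        if len(box_fields) < 3:
            raise ParseError(f"malformed box line: {lines[box_line_idx]!r}")
        try:
            box = [float(box_fields[k]) for k in range(3)]
        except ValueError as exc:
            raise ParseError(f"malformed box line: {lines[box_line_idx]!r}") from exc
        rows = []
        for ln in atom_lines:
            try:
                mol_id = int(ln[0:5])
                resname = ln[5:10].strip()
                atomname = ln[10:15].strip()
                x = float(ln[20:28])
                y = float(ln[28:36])
                z = float(ln[36:44])
            except ValueError as exc:
                raise ParseError(f"malformed GRO atom line: {ln!r}") from exc
            key = (resname, atomname)
            if key not in lookup_cache:
                lookup_cache[key] = role_map.lookup(resname, atomname)
            species, role, chain_id, carbon_index = lookup_cache[key]
            if species == "OTHER" and role == "other":
                n_unmapped += 1
            rows.append((mol_id, species, role, chain_id, carbon_index, x, y, z))
        frames.append(rows)
        boxes.append(box)
        pos = box_line_idx + 1
    if not frames:
        raise ParseError(f"no frames found in GRO file {path}")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise ParseError("inconsistent particle count across GRO frames")
    records = []
    for fi, rows in enumerate(frames):
        for r in rows:
            records.append((fi,) + r)
    df = pd.DataFrame(records, columns=list(TABLE_COLUMNS))
    ens = ParticleEnsemble(df, np.asarray(boxes, dtype=float))
    ens.metadata["n_unmapped"] = n_unmapped // len(frames)
    if recenter:
        recenter_ensemble(ens)
    ens.validate()
    return ens


def write_gro_frames(ens: ParticleEnsemble, path, title: str = "memdiffkit") -> None:
    """Write an ensemble as a multi-frame concatenated GRO file.

    Internal z coordinates are midplane-relative; GRO stores positive box
    coordinates, so z is shifted by +Lz/2 and wrapped on output.  Reading the
    file back with :func:`canonical_role_map` and recentering recovers the
    original ensemble to GRO precision (1e-3 nm).
    """
    ens.validate()
    with open(path, "w", encoding="utf-8") as fh:
        for fi in range(ens.n_frames):
            frame = ens.table[ens.table["frame"] == fi]
            Lx, Ly, Lz = ens.boxes[fi]
            fh.write(f"{title} frame {fi}\n{len(frame)}\n")
            atom_serial = 0
            for row in frame.itertuples(index=False):
                atom_serial += 1
                name = _atom_name(row.role, row.chain_id, row.carbon_index)
                res = _RESNAME[row.species]
                x = row.x % Lx
                y = row.y % Ly
                z = (row.z + Lz / 2.0) % Lz
                fh.write(
                    f"{row.mol_id % 100000:5d}{res:<5s}{name:>5s}"
                    f"{atom_serial % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{Lx:10.5f}{Ly:10.5f}{Lz:10.5f}\n")


def recenter_ensemble(ens: ParticleEnsemble) -> None:
    """Recenter frames in place: phosphate COM at z = 0, wrapped coordinates.

    x and y are wrapped into [0, L); z into [-Lz/2, Lz/2).  Frames without
    phosphate particles are shifted by -Lz/2 (i.e. assumed box-centred).
    """
    table = ens.table
    frame_col = table["frame"].to_numpy()
    z = table["z"].to_numpy(dtype=float).copy()
    x = table["x"].to_numpy(dtype=float).copy()
    y = table["y"].to_numpy(dtype=float).copy()
    is_phos = (table["role"] == "phosphate").to_numpy()
    for fi in range(ens.n_frames):
        Lx, Ly, Lz = ens.boxes[fi]
        in_frame = frame_col == fi
        sel = in_frame & is_phos
        if sel.any():
            shift = z[sel].mean()
        else:
            shift = Lz / 2.0
        zf = z[in_frame] - shift
        zf = (zf + Lz / 2.0) % Lz - Lz / 2.0
        z[in_frame] = zf
        x[in_frame] = x[in_frame] % Lx
        y[in_frame] = y[in_frame] % Ly
    table["x"] = x
    table["y"] = y
    table["z"] = z


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def write_report(results: dict, out_dir, stem: str = "metrics") -> tuple[Path, Path]:
    """Write a metric collection as machine-readable JSON + tabular TSV.

    ``results`` maps metric name to an IntervalEstimate-like object (having
    ``value``/``lower``/``upper``/``method``/``n`` attributes), a plain
    number, or a dict already in report form.  Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {}
    for name, res in sorted(results.items()):
        if hasattr(res, "value") and hasattr(res, "lower"):
            payload[name] = {
                "value": float(res.value),
                "lower": float(res.lower),
                "upper": float(res.upper),
                "method": str(res.method),
                "n": int(res.n),
            }
        elif isinstance(res, dict):
            payload[name] = res
        else:
            payload[name] = {"value": float(res)}
    json_path = out_dir / f"{stem}.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")
    tsv_path = out_dir / f"{stem}.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("metric\tvalue\tlower\tupper\tmethod\tn\n")
        for name, entry in sorted(payload.items()):
            fh.write(
                "\t".join(
                    [
                        name,
                        _fmt(entry.get("value")),
                        _fmt(entry.get("lower")),
                        _fmt(entry.get("upper")),
                        str(entry.get("method", "")),
                        str(entry.get("n", "")),
                    ]
                )
                + "\n"
            )
    return json_path, tsv_path


def _fmt(v) -> str:
    if v is None:
        return ""
    return f"{float(v):.10g}"
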