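"""Trajectory formats: multi-model PDB (via biotite) and concatenated XYZ,
plus a YAML provenance sidecar carrying sampler parameters and seeds.

Every conformation is written as one model with four beads per residue
(N, CA, C and the side-chain bead as CB), chain A, absolute residue
numbering.  Reading a trajectory reconstructs an :class:`Ensemble`;
dihedrals are re-extracted from coordinates (phi of the first residue and
psi of the last are not coordinate-encoded and come back as NaN).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from idrens import geometry
from idrens.sampler import Ensemble, InteractionFlags, SamplerParams
from idrens.sequences import PeptideSequence

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

PDB_ATOM_NAMES = ("N", "CA", "C", "CB")
PDB_ELEMENTS = ("N", "C", "C", "C")


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory file."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".provenance.yaml")


def _write_sidecar(ens: Ensemble, path: Path) -> None:
    p = ens.params
    payload = {
        "sequence": ens.sequence.residues,
        "name": ens.sequence.name,
        "start_number": ens.sequence.start_number,
        "n_conformations": len(ens),
        "seeds": list(ens.seeds),
        "acceptance_rate": float(ens.acceptance_rate),
        "params": {
            "n_runs": p.n_runs,
            "production_steps": p.production_steps,
            "equilibration_steps": p.equilibration_steps,
            "sampling_interval": p.sampling_interval,
            "droplet_radius": p.droplet_radius,
            "temperature": p.temperature,
            "ionic_strength": p.ionic_strength,
            "helix_propensity_overrides": dict(p.helix_propensity_overrides),
            "interactions": p.interactions.as_dict(),
            "base_seed": p.base_seed,
        },
    }
    _sidecar_path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _read_sidecar(path: Path):
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    payload = yaml.safe_load(sc.read_text())
    pp = payload["params"]
    params = SamplerParams(
        n_runs=pp["n_runs"],
        production_steps=pp["production_steps"],
        equilibration_steps=pp["equilibration_steps"],
        sampling_interval=pp["sampling_interval"],
        droplet_radius=pp["droplet_radius"],
        temperature=pp["temperature"],
        ionic_strength=pp["ionic_strength"],
        helix_propensity_overrides=pp["helix_propensity_overrides"],
        interactions=InteractionFlags(**pp["interactions"]),
        base_seed=pp["base_seed"],
    )
    return payload, params


def write_trajectory(ens: Ensemble, path: str | Path) -> Path:
    """Write a multi-model PDB (``.pdb``) or concatenated XYZ (``.xyz``)
    with a provenance sidecar next to it."""
    path = Path(path)
    coords = ens.coordinates()
    if path.suffix == ".pdb":
        _write_pdb(ens, coords, path)
    elif path.suffix == ".xyz":
        _write_xyz(ens, coords, path)
    else:
        raise ValueError(f"unsupported trajectory format: {path.suffix!r}")
    _write_sidecar(ens, path)
    return path


def _template_atoms(seq: PeptideSequence) -> struc.AtomArray:
    n_res = len(seq)
    n_atoms = n_res * geometry.BEADS_PER_RESIDUE
    arr = struc.AtomArray(n_atoms)
    arr.chain_id = np.full(n_atoms, "A")
    res_ids = np.repeat(np.arange(seq.start_number, seq.start_number + n_res), 4)
    arr.res_id = res_ids
    arr.res_name = np.repeat([THREE_LETTER[r] for r in seq.residues], 4)
    arr.atom_name = np.tile(np.array(PDB_ATOM_NAMES), n_res)
    arr.element = np.tile(np.array(PDB_ELEMENTS), n_res)
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    return arr


def _write_pdb(ens: Ensemble, coords: np.ndarray, path: Path) -> None:
    template = _template_atoms(ens.sequence)
    stack = struc.from_template(template, coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _write_xyz(ens: Ensemble, coords: np.ndarray, path: Path) -> None:
    n_atoms = coords.shape[1]
    labels = [geometry.ATOM_NAMES[a % 4] for a in range(n_atoms)]
    with open(path, "w") as fh:
        for k in range(coords.shape[0]):
            fh.write(f"{n_atoms}\n")
            fh.write(f"model {k + 1} {ens.sequence.name}\n")
            for a in range(n_atoms):
                x, y, z = coords[k, a]
                fh.write(f"{labels[a]} {x:.6f} {y:.6f} {z:.6f}\n")


def _dihedrals_from_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (phi, psi) extraction for a (n_conf, 4*n_res, 3) stack."""
    N = coords[:, 0::4]
    CA = coords[:, 1::4]
    C = coords[:, 2::4]

    def tors(p0, p1, p2, p3):
        b0 = p1 - p0
        b1 = p2 - p1
        b2 = p3 - p2
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
        m1 = np.cross(n1, b1n)
        x = (n1 * n2).sum(axis=-1)
        y = (m1 * n2).sum(axis=-1)
        return np.degrees(np.arctan2(y, x))

    n_conf, n_res = N.shape[0], N.shape[1]
    phi = np.full((n_conf, n_res), np.nan)
    psi = np.full((n_conf, n_res), np.nan)
    phi[:, 1:] = tors(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
    psi[:, :-1] = tors(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    return phi, psi


def _ensemble_from_coords(coords: np.ndarray, seq: PeptideSequence,
                          path: Path) -> Ensemble:
    meta = _read_sidecar(path)
    if meta is not None:
        payload, params = meta
        seeds = tuple(payload.get("seeds", ()))
        acc = float(payload.get("acceptance_rate", float("nan")))
    else:
        params = None
        seeds = ()
        acc = float("nan")
    phi, psi = _dihedrals_from_coords(coords)
    ens = Ensemble(
        sequence=seq,
        phi=phi,
        psi=psi,
        params=params,
        run_ids=np.zeros(coords.shape[0], dtype=np.int64),
        seeds=seeds,
        acceptance_rate=acc,
    )
    ens._coords = coords
    return ens


def read_trajectory(path: str | Path) -> Ensemble:
    """Read a multi-model PDB or XYZ trajectory back into an ensemble."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TrajectoryError(f"{path}: empty trajectory file")
    if path.suffix == ".pdb":
        return _read_pdb(path)
    if path.suffix == ".xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported trajectory format: {path.suffix!r}")


def _read_pdb(path: Path) -> Ensemble:
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises format-specific errors
        raise TrajectoryError(f"{path}: failed to parse PDB ({exc})") from exc
    if stack.array_length() == 0:
        raise TrajectoryError(f"{path}: no atoms in file")
    first = stack[0]
    res_ids = first.res_id[first.atom_name == "CA"]
    res_names = first.res_name[first.atom_name == "CA"]
    try:
        residues = "".join(ONE_LETTER[str(r)] for r in res_names)
    except KeyError as exc:
        raise TrajectoryError(f"{path}: unknown residue name {exc}") from exc
    seq = PeptideSequence(residues, start_number=int(res_ids[0]), name=path.stem)
    n_expected = len(seq) * geometry.BEADS_PER_RESIDUE
    if first.array_length() != n_expected:
        raise TrajectoryError(
            f"{path}: expected {n_expected} beads per model, "
            f"found {first.array_length()}"
        )
    coords = np.asarray(stack.coord, dtype=np.float64)
    return _ensemble_from_coords(coords, seq, path)


def _read_xyz(path: Path) -> Ensemble:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_lines = len(lines)
    while ln < n_lines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n_atoms = int(lines[ln].strip())
        except ValueError:
            raise TrajectoryError(f"{path}:{ln + 1}: expected atom count")
        if ln + 1 + n_atoms + 1 > n_lines:
            raise TrajectoryError(f"{path}:{ln + 1}: truncated frame")
        block = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = lines[ln + 2 + a].split()
            if len(parts) != 4:
                raise TrajectoryError(f"{path}:{ln + 3 + a}: malformed atom record")
            block[a] = [float(v) for v in parts[1:]]
        frames.append(block)
        ln += 2 + n_atoms
    if not frames:
        raise TrajectoryError(f"{path}: empty trajectory file")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise TrajectoryError(f"{path}: inconsistent atom counts across frames: {sorted(counts)}")
    coords = np.stack(frames)
    meta = _read_sidecar(path)
    if meta is not None:
        payload, _ = meta
        seq = PeptideSequence(payload["sequence"], payload["start_number"],
                              payload.get("name", path.stem))
    else:
        n_res = coords.shape[1] // geometry.BEADS_PER_RESIDUE
        seq = PeptideSequence("A" * n_res, 38, path.stem)  # sequence unknown in bare XYZ
    return _ensemble_from_coords(coords, seq, path)
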