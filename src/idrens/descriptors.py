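"""Per-conformation and per-ensemble structural descriptors.

Radius of gyration and asphericity are computed over all beads (backbone +
side chain); distance maps use CA beads only; helicity is dihedral-based
(helical Ramachandran basin membership with a minimum run length of 4,
one helical turn).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from idrens.sampler import Conformation, Ensemble, HELICAL_BASIN

#: Default "C-terminal region" (absolute residue numbers, inclusive) over
#: which region-averaged helicity is reported.
CTERM_REGION = (50, 59)

#: Minimum number of consecutive helical residues for a residue to count as
#: part of a helix (one turn).
MIN_HELIX_RUN = 4


def _bead_array(conf_or_coords) -> np.ndarray:
    if isinstance(conf_or_coords, Conformation):
        return conf_or_coords.coords
    return np.asarray(conf_or_coords, dtype=float)


def radius_of_gyration(conf: Conformation | np.ndarray) -> float:
    """Mass-uniform radius of gyration over all beads (Angstrom)."""
    xyz = _bead_array(conf)
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def gyration_tensor(conf: Conformation | np.ndarray) -> np.ndarray:
    xyz = _bead_array(conf)
    centered = xyz - xyz.mean(axis=0)
    return centered.T @ centered / len(xyz)


def asphericity(conf: Conformation | np.ndarray) -> float:
    """Normalized shape anisotropy: 0 for spherically symmetric bead sets,
    1 for collinear ones.

    delta = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2 with l_k the
    gyration-tensor eigenvalues; evaluated eigenvalue-free through the
    tensor invariants.  All-coincident beads give 0 by convention.
    """
    t = gyration_tensor(conf)
    tr = float(np.trace(t))
    if tr == 0.0:
        return 0.0
    # sum of pairwise eigenvalue products = (tr^2 - tr(T^2)) / 2
    m2 = (tr * tr - float(np.trace(t @ t))) / 2.0
    return 1.0 - 3.0 * m2 / (tr * tr)


def asphericity_eig(conf: Conformation | np.ndarray) -> float:
    """Eigen-decomposition route for the same quantity (cross-check path)."""
    lam = np.linalg.eigvalsh(gyration_tensor(conf))
    s = lam.sum()
    if s == 0.0:
        return 0.0
    return float(1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / s**2)


def end_to_end_distance(conf: Conformation) -> float:
    """CA(first) to CA(last) distance (Angstrom)."""
    ca = conf.ca_coords
    return float(np.linalg.norm(ca[-1] - ca[0]))


def in_helical_basin(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Boolean basin membership, elementwise; NaN dihedrals are non-helical."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    lo_p, hi_p, lo_s, hi_s = HELICAL_BASIN
    with np.errstate(invalid="ignore"):
        return (phi >= lo_p) & (phi <= hi_p) & (psi >= lo_s) & (psi <= hi_s)


def helical_residues(phi: np.ndarray, psi: np.ndarray,
                     min_run: int = MIN_HELIX_RUN) -> np.ndarray:
    """Residues in the helical basin AND inside a run of >= min_run such
    residues.  Accepts (n_res,) or (n_conf, n_res) arrays."""
    single = np.asarray(phi).ndim == 1
    basin = np.atleast_2d(in_helical_basin(phi, psi))
    n_conf, n_res = basin.shape
    if n_res < min_run:
        out = np.zeros_like(basin)
    else:
        windows = np.ones((n_conf, n_res - min_run + 1), dtype=bool)
        for k in range(min_run):
            windows &= basin[:, k:k + n_res - min_run + 1]
        out = np.zeros_like(basin)
        for j in range(n_res - min_run + 1):
            out[:, j:j + min_run] |= windows[:, j:j + 1]
    return out[0] if single else out


def per_residue_helicity(ens: Ensemble, min_run: int = MIN_HELIX_RUN) -> np.ndarray:
    """Fraction of conformations in which each residue is helical."""
    return helical_residues(ens.phi, ens.psi, min_run).mean(axis=0)


def region_mean_helicity(ens: Ensemble, region: tuple[int, int] = CTERM_REGION,
                         min_run: int = MIN_HELIX_RUN) -> float:
    """Mean per-residue helicity over an absolute-numbered residue range."""
    f = per_residue_helicity(ens, min_run)
    start = ens.sequence.start_number
    lo, hi = region
    i0, i1 = lo - start, hi - start + 1
    if i0 < 0 or i1 > ens.n_res or i0 >= i1:
        raise ValueError(f"region {region} outside sequence numbering")
    return float(f[i0:i1].mean())


def mean_distance_map(ens: Ensemble) -> np.ndarray:
    """<d_ij> over CA beads, averaged across conformations (Angstrom)."""
    ca = ens.ca_coordinates()
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)).mean(axis=0)


def instantaneous_distance_maps(ens: Ensemble) -> np.ndarray:
    """Per-conformation CA distance maps, shape (n_conf, n_res, n_res)."""
    ca = ens.ca_coordinates()
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class ScalingMap:
    """Ratio of mean inter-residue distances against an excluded-volume
    reference; the diagonal is flagged NaN (self-distances are zero)."""

    ratio: np.ndarray

    def mean_offdiagonal_deviation(self, min_separation: int = 3) -> float:
        """mean |R_ij - 1| over pairs with |i - j| >= min_separation."""
        n = self.ratio.shape[0]
        i, j = np.triu_indices(n, k=min_separation)
        return float(np.abs(self.ratio[i, j] - 1.0).mean())


def scaling_map(ens: Ensemble, ev_ens: Ensemble) -> ScalingMap:
    """Element-wise <d_ij> ratio of an ensemble against its excluded-volume
    reference.  Requires equal sequence lengths and a sterics-only reference."""
    if ens.n_res != ev_ens.n_res:
        raise ValueError("ensembles have different sequence lengths")
    flags = ev_ens.params.interactions
    if flags.electrostatics or flags.helix_bias or not flags.sterics:
        raise ValueError("reference ensemble must be sampled with sterics only")
    num = mean_distance_map(ens)
    den = mean_distance_map(ev_ens)
    ratio = np.full_like(num, np.nan)
    off = ~np.eye(num.shape[0], dtype=bool)
    ratio[off] = num[off] / den[off]
    return ScalingMap(ratio=ratio)


@dataclass
class DescriptorTable:
    """All descriptors of one ensemble.

    ``per_conformation`` has one row per conformation (rg, asphericity,
    end_to_end); ``helicity`` is the per-residue helical fraction;
    ``mean_map`` is the CA mean distance map.
    """

    name: str
    start_number: int
    per_conformation: pd.DataFrame
    helicity: np.ndarray
    mean_map: np.ndarray

    @property
    def n_res(self) -> int:
        return len(self.helicity)

    def __len__(self) -> int:
        return len(self.per_conformation)

    def write(self, directory: str | Path, prefix: str | None = None) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix if prefix is not None else self.name
        residues = np.arange(self.start_number, self.start_number + self.n_res)
        paths = []
        p = directory / f"{prefix}_conformations.csv"
        self.per_conformation.to_csv(p, index_label="conformation")
        paths.append(p)
        p = directory / f"{prefix}_helicity.csv"
        pd.DataFrame({"residue": residues, "helicity": self.helicity}).to_csv(p, index=False)
        paths.append(p)
        p = directory / f"{prefix}_distance_map.csv"
        pd.DataFrame(self.mean_map, index=residues, columns=residues).to_csv(p)
        paths.append(p)
        return paths

    @classmethod
    def read(cls, directory: str | Path, prefix: str) -> "DescriptorTable":
        directory = Path(directory)
        per_conf = pd.read_csv(directory / f"{prefix}_conformations.csv",
                               index_col="conformation")
        hel = pd.read_csv(directory / f"{prefix}_helicity.csv")
        dmap = pd.read_csv(directory / f"{prefix}_distance_map.csv", index_col=0)
        return cls(
            name=prefix,
            start_number=int(hel["residue"].iloc[0]),
            per_conformation=per_conf,
            helicity=hel["helicity"].to_numpy(),
            mean_map=dmap.to_numpy(),
        )


def compute_descriptors(ens: Ensemble, name: str | None = None) -> DescriptorTable:
    """Full descriptor table for one ensemble."""
    coords = ens.coordinates()
    centered = coords - coords.mean(axis=1, keepdims=True)
    rg = np.sqrt((centered**2).sum(axis=2).mean(axis=1))

    # gyration-tensor invariants, vectorized over conformations
    n_beads = coords.shape[1]
    t = np.einsum("kai,kaj->kij", centered, centered) / n_beads
    tr = np.trace(t, axis1=1, axis2=2)
    tr2 = np.einsum("kij,kji->k", t, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(tr > 0, 1.0 - 3.0 * (tr * tr - tr2) / (2.0 * tr * tr), 0.0)

    ca = ens.ca_coordinates()
    ree = np.linalg.norm(ca[:, -1] - ca[:, 0], axis=1)

    per_conf = pd.DataFrame({"rg": rg, "asphericity": delta, "end_to_end": ree})
    return DescriptorTable(
        name=name or ens.sequence.name or "ensemble",
        start_number=ens.sequence.start_number,
        per_conformation=per_conf,
        helicity=per_residue_helicity(ens),
        mean_map=mean_distance_map(ens),
    )
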