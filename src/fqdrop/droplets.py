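"""Trajectory handling, droplet cutting and conformational/hydration analysis.

A production trajectory is reduced to solute-centered spherical droplets —
finite clusters of whole water molecules within a fixed radius (18 Å by
default) of the solute center — which downstream embedding calculations
consume.  The same frames feed the standard conformational descriptors:
site–site radial distribution functions with running coordination numbers,
dihedral distributions, and GROMOS-style RMSD neighbor clustering.

GRO/PDB dialects are read through MDAnalysis (residues define molecules);
the XYZ dialect is parsed directly so that molecule sidecar maps and
line-numbered parse errors are available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ContractError, FormatError, ParseError, TopologyError

logger = logging.getLogger(__name__)

DEFAULT_DROPLET_RADIUS = 18.0   # Å
DEFAULT_CLUSTER_THRESHOLD_NM = 0.11

__all__ = [
    "TrajectoryFrame",
    "Droplet",
    "RDFResult",
    "DihedralSeries",
    "ClusterResult",
    "read_frames",
    "write_xyz_frames",
    "cut_droplet",
    "droplet_frame",
    "rdf",
    "dihedral_angle",
    "dihedral_distribution",
    "cluster_rmsd",
    "resolve_selection",
]


@dataclass
class TrajectoryFrame:
    """One snapshot: positions (Å), element symbols, molecule ids, optional box (Å)."""

    time: float
    positions: np.ndarray
    elements: list
    molecule_ids: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ContractError("frame positions must be finite")
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if len(self.elements) != len(self.positions) or len(self.molecule_ids) != len(self.positions):
            raise ContractError("elements/molecule_ids must match the atom count")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self):
        return len(self.elements)


@dataclass
class Droplet:
    """A solute-centered sphere of whole water molecules cut from a frame."""

    solute_indices: np.ndarray
    retained_molecules: np.ndarray
    radius: float
    center: np.ndarray


@dataclass
class RDFResult:
    r: np.ndarray          # bin centers, Å
    g: np.ndarray          # dimensionless
    rcn: np.ndarray        # running coordination number at bin upper edges
    bulk_density: float    # atoms/Å³
    reference: object = None
    target: object = None


@dataclass
class DihedralSeries:
    indices: tuple
    angles: np.ndarray       # degrees in (−180, 180], one per usable frame
    bin_edges: np.ndarray
    counts: np.ndarray
    skipped_frames: list = field(default_factory=list)


@dataclass
class ClusterResult:
    membership: np.ndarray     # cluster index per frame, 0 = most populated
    representatives: list      # frame index per cluster
    populations: np.ndarray    # percent, sums to 100


# ---------------------------------------------------------------------------
# reading and writing frames
# ---------------------------------------------------------------------------

def _read_xyz(path, molecule_map=None):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_expected = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{ln + 1}: expected an atom count") from None
        if n_expected is None:
            n_expected = nat
        elif nat != n_expected:
            raise FormatError(f"{path}:{ln + 1}: atom count changed from {n_expected} to {nat}")
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        elements, pos = [], []
        for k in range(nat):
            idx = ln + 2 + k
            if idx >= len(lines):
                raise ParseError(f"{path}:{idx + 1}: truncated frame")
            parts = lines[idx].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{idx + 1}: expected 'element x y z'")
            try:
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError(f"{path}:{idx + 1}: malformed coordinate") from None
            elements.append(parts[0])
        time = float(len(frames))
        for tok in comment.split():
            if tok.startswith("t="):
                try:
                    time = float(tok[2:])
                except ValueError:
                    pass
        mol_ids = _xyz_molecule_ids(elements, molecule_map)
        frames.append(TrajectoryFrame(time=time, positions=np.array(pos),
                                      elements=elements, molecule_ids=mol_ids))
        ln += 2 + nat
    return frames


def _xyz_molecule_ids(elements, molecule_map):
    n = len(elements)
    if molecule_map is not None:
        ids = np.asarray(molecule_map, dtype=int)
        if ids.shape != (n,):
            raise ContractError("molecule map length must equal the atom count")
        return ids
    # infer rigid-water grouping when the file is a plain O,H,H repetition
    if n % 3 == 0 and all(
        elements[3 * i] == "O" and elements[3 * i + 1] == "H" and elements[3 * i + 2] == "H"
        for i in range(n // 3)
    ):
        return np.repeat(np.arange(n // 3), 3)
    return np.arange(n)


def _read_mdanalysis(path, fmt, stride):
    import MDAnalysis as mda

    u = mda.Universe(path, format=fmt)
    try:
        elements = [a.element if a.element else a.name[0] for a in u.atoms]
    except Exception:
        elements = [a.name[0] for a in u.atoms]
    mol_ids = np.asarray(u.atoms.resindices, dtype=int)
    frames = []
    for ts in u.trajectory[::stride]:
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.asarray(ts.dimensions[:3], dtype=float)
        frames.append(TrajectoryFrame(
            time=float(ts.time) if ts.time is not None else float(ts.frame),
            positions=np.array(ts.positions, dtype=float),
            elements=elements,
            molecule_ids=mol_ids,
            box=box,
        ))
    return frames


def read_frames(path, format=None, stride=1, molecule_map=None):
    """Read a multi-frame trajectory (xyz, gro or pdb) with an optional stride.

    ``molecule_map`` (xyz only) is a per-atom molecule-id list or a path to
    a JSON sidecar containing one; without it, plain O,H,H-repetition files
    are grouped into waters and anything else gets one molecule per atom.
    Frames come back in file order, strided as ``frames[::stride]``.
    """
    if stride < 1:
        raise ContractError("stride must be a positive frame count")
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("xyz", "gro", "pdb"):
        raise ContractError(f"unsupported trajectory format {fmt!r}")
    if fmt == "xyz":
        if isinstance(molecule_map, (str, bytes)) or hasattr(molecule_map, "read"):
            with open(molecule_map) as fh:
                molecule_map = json.load(fh)
        return _read_xyz(path, molecule_map)[::stride]
    return _read_mdanalysis(path, fmt.upper(), stride)


def write_xyz_frames(path, frames, precision=4):
    """Write frames as multi-frame XYZ (fixed decimal precision, Å)."""
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"t={fr.time}\n")
            for el, (x, y, z) in zip(fr.elements, fr.positions):
                fh.write(f"{el} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")


# ---------------------------------------------------------------------------
# droplet cutting
# ---------------------------------------------------------------------------

def cut_droplet(frame, solute_selection, radius=DEFAULT_DROPLET_RADIUS,
                center_mode="geometric", masses=None):
    """Cut a solute-centered droplet of whole waters from one frame.

    The center is the solute geometric center (or center of mass with
    ``center_mode="mass"`` and per-atom ``masses``).  A water molecule is
    retained if and only if its oxygen lies within ``radius`` of the center
    (closed ball), and retained molecules are always kept whole.
    """
    solute = np.asarray(resolve_selection(frame, solute_selection), dtype=int)
    if solute.size == 0:
        raise ContractError("solute selection is empty")
    if center_mode == "geometric":
        center = frame.positions[solute].mean(axis=0)
    elif center_mode == "mass":
        if masses is None:
            raise ContractError("center_mode='mass' requires per-atom masses")
        m = np.asarray(masses, dtype=float)[solute]
        center = (m[:, None] * frame.positions[solute]).sum(axis=0) / m.sum()
    else:
        raise ContractError(f"unknown center_mode {center_mode!r}")

    solute_mols = set(frame.molecule_ids[solute].tolist())
    retained = []
    for mol in np.unique(frame.molecule_ids):
        if mol in solute_mols:
            continue
        members = np.flatnonzero(frame.molecule_ids == mol)
        oxygens = [i for i in members if frame.elements[i] == "O"]
        if not oxygens:
            raise TopologyError(f"solvent molecule {mol} has no oxygen atom")
        if np.linalg.norm(frame.positions[oxygens[0]] - center) <= radius:
            retained.append(mol)
    return Droplet(
        solute_indices=solute,
        retained_molecules=np.asarray(retained, dtype=int),
        radius=float(radius),
        center=center,
    )


def droplet_frame(frame, droplet):
    """Materialize a droplet as a standalone frame (solute first, then waters)."""
    keep = list(droplet.solute_indices)
    for mol in droplet.retained_molecules:
        keep.extend(np.flatnonzero(frame.molecule_ids == mol).tolist())
    keep = np.asarray(keep, dtype=int)
    return TrajectoryFrame(
        time=frame.time,
        positions=frame.positions[keep],
        elements=[frame.elements[i] for i in keep],
        molecule_ids=frame.molecule_ids[keep],
        box=None,
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def resolve_selection(frame, selection):
    """Resolve a selection to atom indices.

    Accepts an index sequence, a sequence of element symbols (all matching
    atoms), or a single element symbol.
    """
    if isinstance(selection, str):
        selection = [selection]
    selection = list(selection)
    if selection and all(isinstance(s, str) for s in selection):
        wanted = set(selection)
        return np.array([i for i, el in enumerate(frame.elements) if el in wanted], dtype=int)
    return np.asarray(selection, dtype=int)


# ---------------------------------------------------------------------------
# RDF / RCN
# ---------------------------------------------------------------------------

def _minimum_image(d, box):
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def rdf(frames, selection_a, selection_b, bin_width=0.05, r_max=10.0,
        bulk_density=None):
    """Site–site radial distribution function and running coordination number.

    g(r) normalizes pair counts by the spherical-shell volume and the bulk
    density of the target selection (taken as N_b/V from the orthorhombic
    box, or supplied for boxless systems; droplets are not valid input).
    rcn(r) is the cumulative mean number of b neighbors around an a site.
    """
    frames = list(frames)
    if not frames:
        raise ContractError("need at least one frame")
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_a = n_b = None
    for fr in frames:
        ia = resolve_selection(fr, selection_a)
        ib = resolve_selection(fr, selection_b)
        if ia.size == 0 or ib.size == 0:
            raise ContractError("empty RDF selection")
        n_a, n_b = ia.size, ib.size
        d = fr.positions[ia][:, None, :] - fr.positions[ib][None, :, :]
        d = _minimum_image(d, fr.box)
        r = np.linalg.norm(d, axis=-1)
        same = np.intersect1d(ia, ib)
        if same.size:
            mask_a = np.isin(ia, same)
            mask_b = np.isin(ib, same)
            sub = r[np.ix_(mask_a, mask_b)]
            np.fill_diagonal(sub, np.inf)
            r[np.ix_(mask_a, mask_b)] = sub
        counts += np.histogram(r.ravel(), bins=edges)[0]
    counts /= len(frames)

    if bulk_density is None:
        boxes = [fr.box for fr in frames]
        if any(b is None for b in boxes):
            raise ContractError("no box on some frames: supply bulk_density explicitly")
        vol = float(np.mean([np.prod(b) for b in boxes]))
        bulk_density = n_b / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (n_a * shell * bulk_density)
    rcn = np.cumsum(counts) / n_a
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g, rcn=rcn, bulk_density=float(bulk_density),
                     reference=selection_a, target=selection_b)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3):
    """IUPAC-signed dihedral (degrees in (−180, 180]) for four points.

    Raises :class:`GeometryError`-like ContractError when the middle bond
    is degenerate (colinear atoms)."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm = np.linalg.norm
    if norm(n1) < 1e-10 * max(norm(b1) * norm(b2), 1e-300) or \
       norm(n2) < 1e-10 * max(norm(b2) * norm(b3), 1e-300):
        raise ContractError("colinear atoms: dihedral undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / norm(b2)))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_distribution(frames, tuples, bin_width=5.0):
    """Per-frame dihedral series and histograms for each four-atom tuple.

    Frames where a dihedral is numerically undefined (colinear middle
    atoms) are skipped for that tuple and logged; the histogram counts sum
    to the number of usable frames.
    """
    frames = list(frames)
    results = []
    edges = np.arange(-180.0, 180.0 + bin_width * 0.5, bin_width)
    for tup in tuples:
        if len(set(tup)) != 4:
            raise ContractError(f"dihedral tuple {tup} must hold four distinct indices")
        angles, skipped = [], []
        for k, fr in enumerate(frames):
            p = fr.positions
            try:
                angles.append(dihedral_angle(p[tup[0]], p[tup[1]], p[tup[2]], p[tup[3]]))
            except ContractError:
                skipped.append(k)
                logger.warning("frame %d: dihedral %s undefined, frame skipped", k, tup)
        angles = np.asarray(angles)
        counts = np.histogram(angles, bins=edges)[0]
        results.append(DihedralSeries(indices=tuple(tup), angles=angles,
                                      bin_edges=edges, counts=counts,
                                      skipped_frames=skipped))
    return results


# ---------------------------------------------------------------------------
# RMSD clustering (GROMOS neighbor counting)
# ---------------------------------------------------------------------------

def superposed_rmsd(a, b):
    """Mass-free optimal-superposition RMSD between two coordinate sets, Å."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / np.sqrt(len(a)))


def cluster_rmsd(frames, threshold_nm=DEFAULT_CLUSTER_THRESHOLD_NM, selection=None):
    """GROMOS-style neighbor-counting clustering on superposed RMSD.

    The frame with the most neighbors within ``threshold_nm`` (ties: the
    earliest frame index) becomes a cluster representative; it and its
    neighbors are removed and the procedure repeats.  Populations are
    cluster sizes as percentages of the frame count.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ContractError("need at least two frames to cluster")
    if threshold_nm <= 0:
        raise ContractError("threshold must be positive")
    sel = resolve_selection(frames[0], selection) if selection is not None \
        else np.arange(frames[0].n_atoms)
    coords = [fr.positions[sel] for fr in frames]
    n = len(frames)
    within = np.zeros((n, n), dtype=bool)
    for i in range(n):
        within[i, i] = True
        for j in range(i + 1, n):
            rmsd_nm = superposed_rmsd(coords[i], coords[j]) / 10.0
            within[i, j] = within[j, i] = rmsd_nm <= threshold_nm

    membership = np.full(n, -1, dtype=int)
    representatives = []
    alive = np.ones(n, dtype=bool)
    cluster = 0
    while alive.any():
        neigh = (within & alive[None, :]).sum(axis=1)
        neigh[~alive] = -1
        center = int(np.argmax(neigh))  # argmax returns the earliest on ties
        members = np.flatnonzero(within[center] & alive)
        membership[members] = cluster
        representatives.append(center)
        alive[members] = False
        cluster += 1
    sizes = np.bincount(membership, minlength=cluster)
    populations = 100.0 * sizes / n
    return ClusterResult(membership=membership, representatives=representatives,
                         populations=populations)
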