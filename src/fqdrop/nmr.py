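"""Chemical shifts, coupled spin-system simulation and inter-model statistics.

Shieldings σ are referenced to a standard (TMS) via δ = σ_ref − σ.  Coupled
¹H spectra are simulated from the isotropic spin Hamiltonian

    H = Σ_i ν_i I_z,i + Σ_{i<j} J_ij I_i·I_j      (ν_i = δ_i × spectrometer MHz, in Hz)

diagonalized exactly in the 2^N product basis (block-diagonal in total
magnetization), emitting single-quantum transitions with intensities
|⟨f|Σ_i I_x,i|s⟩|².  Beyond the 12-spin cap a first-order multiplet
construction is available.  Equivalent nuclei need no special handling:
equal shifts make their mutual coupling spectroscopically invisible in the
exact treatment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .spectra import LineShapeKernel, Spectrum, StickSpectrum, convolve

EXACT_SPIN_CAP = 12
PLANCK_EV_S = 4.135667696e-15

__all__ = [
    "ShiftTable",
    "SpinSystem",
    "NMRSpectrum",
    "shielding_to_shift",
    "simulate_coupled_spectrum",
    "first_order_lines",
    "model_deviation",
    "fwhm_ev_to_ppm",
]


@dataclass
class ShiftTable:
    """Per-nucleus shift or shielding values for one solvent model.

    ``entries`` maps a nucleus label to ``(isotope, value_ppm)``; ``kind``
    is uniform over the table: either ``shift_ppm`` or ``shielding_ppm``.
    """

    entries: dict
    kind: str = "shift_ppm"
    model: str = ""

    def __post_init__(self):
        if self.kind not in ("shift_ppm", "shielding_ppm"):
            raise ContractError(f"unknown table kind {self.kind!r}")

    def labels(self, isotope=None):
        return [l for l, (iso, _) in self.entries.items() if isotope is None or iso == isotope]

    def value(self, label):
        return self.entries[label][1]

    @classmethod
    def from_csv(cls, path, kind="shift_ppm", model=""):
        """Read a ``label,isotope,value`` CSV."""
        entries = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if [h.strip().lower() for h in header[:3]] != ["label", "isotope", "value"]:
                raise ContractError("expected header label,isotope,value")
            for row in reader:
                if row:
                    entries[row[0].strip()] = (row[1].strip(), float(row[2]))
        return cls(entries=entries, kind=kind, model=model)


@dataclass
class SpinSystem:
    """A set of coupled spin-½ nuclei at a stated spectrometer frequency.

    ``shifts_ppm`` maps label → δ (ppm); ``couplings_hz`` maps unordered
    label pairs (stored as sorted tuples) → J (Hz).
    """

    shifts_ppm: dict
    couplings_hz: dict = field(default_factory=dict)
    spectrometer_mhz: float = 600.0

    def __post_init__(self):
        norm = {}
        for (a, b), j in self.couplings_hz.items():
            if a == b:
                raise ContractError(f"self-coupling on {a!r} is not allowed")
            if a not in self.shifts_ppm or b not in self.shifts_ppm:
                raise ContractError(f"coupling ({a!r}, {b!r}) references unknown spins")
            key = tuple(sorted((a, b)))
            if key in norm and norm[key] != j:
                raise ContractError(f"inconsistent duplicate coupling for {key}")
            norm[key] = float(j)
        self.couplings_hz = norm

    @property
    def n_spins(self):
        return len(self.shifts_ppm)

    def without(self, exclude):
        """Copy with the listed spins (e.g. exchangeable N–H protons) removed."""
        keep = {l: d for l, d in self.shifts_ppm.items() if l not in set(exclude)}
        coup = {k: j for k, j in self.couplings_hz.items()
                if k[0] in keep and k[1] in keep}
        return SpinSystem(keep, coup, self.spectrometer_mhz)

    @classmethod
    def from_csv(cls, shifts_path, couplings_path=None, spectrometer_mhz=600.0):
        shifts = {}
        with open(shifts_path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            for row in reader:
                if row:
                    shifts[row[0].strip()] = float(row[-1])
        couplings = {}
        if couplings_path:
            with open(couplings_path, newline="") as fh:
                reader = csv.reader(fh)
                next(reader)
                for row in reader:
                    if row:
                        couplings[(row[0].strip(), row[1].strip())] = float(row[2])
        return cls(shifts, couplings, spectrometer_mhz)


@dataclass
class NMRSpectrum:
    """Transition line list (ppm, intensity) plus the broadened spectrum."""

    lines: list
    spectrum: Spectrum | None
    provenance: dict = field(default_factory=dict)

    @property
    def total_intensity(self):
        return float(sum(i for _, i in self.lines))


def shielding_to_shift(sigma, reference):
    """δ = σ_ref − σ (ppm); works element-wise on arrays."""
    return np.asarray(reference, dtype=float) - np.asarray(sigma, dtype=float)


def fwhm_ev_to_ppm(fwhm_ev, spectrometer_mhz):
    """Convert an energy-unit linewidth to ppm at the stated proton frequency."""
    fwhm_hz = fwhm_ev / PLANCK_EV_S
    return fwhm_hz / (spectrometer_mhz * 1e6)


# ---------------------------------------------------------------------------
# exact diagonalization in magnetization blocks
# ---------------------------------------------------------------------------

def _block_states(n):
    """Basis states (bit set = spin down) grouped by number of down spins."""
    groups = [[] for _ in range(n + 1)]
    for state in range(1 << n):
        groups[state.bit_count()].append(state)
    return groups


def _block_hamiltonian(states, nu, jmat, n):
    index = {s: k for k, s in enumerate(states)}
    dim = len(states)
    H = np.zeros((dim, dim))
    for k, s in enumerate(states):
        m = np.array([0.5 - ((s >> i) & 1) for i in range(n)])
        diag = float(nu @ m)
        for i in range(n):
            for j in range(i + 1, n):
                if jmat[i, j]:
                    diag += jmat[i, j] * m[i] * m[j]
                    if ((s >> i) & 1) != ((s >> j) & 1):
                        t = s ^ (1 << i) ^ (1 << j)   # flip-flop partner
                        H[k, index[t]] += 0.5 * jmat[i, j]
        H[k, k] = diag
    return H


def simulate_coupled_spectrum(system, kernel=None, grid=None, mode="exact",
                              intensity_floor=1e-10):
    """Simulate the 1D spectrum of a coupled spin system.

    ``mode="exact"`` (≤ 12 spins) diagonalizes the isotropic spin
    Hamiltonian and emits allowed single-quantum transitions; ``"first_order"``
    builds multiplets by successive doublet splitting (valid for weak
    coupling Δν ≫ J).  Intensities are raw squared matrix elements; the
    normalization convention is recorded in the provenance.  Pass a
    :class:`~fqdrop.spectra.LineShapeKernel` (FWHM in ppm) and optionally a
    ppm grid to obtain a broadened spectrum.
    """
    n = system.n_spins
    if n == 0:
        raise ContractError("spin system is empty")
    labels = list(system.shifts_ppm)
    nu = np.array([system.shifts_ppm[l] for l in labels]) * system.spectrometer_mhz  # Hz
    jmat = np.zeros((n, n))
    for (a, b), j in system.couplings_hz.items():
        ia, ib = labels.index(a), labels.index(b)
        jmat[ia, ib] = jmat[ib, ia] = j

    if mode == "first_order":
        lines_hz = first_order_lines(system)
    elif mode == "exact":
        if n > EXACT_SPIN_CAP:
            raise ContractError(
                f"{n} spins exceed the exact-diagonalization cap of {EXACT_SPIN_CAP}; "
                "use mode='first_order'"
            )
        lines_hz = _exact_lines(nu, jmat, n, intensity_floor)
    else:
        raise ContractError(f"unknown simulation mode {mode!r}")

    mhz = system.spectrometer_mhz
    lines_ppm = [(f / mhz, inten) for f, inten in lines_hz]
    spectrum = None
    if kernel is not None:
        sticks = StickSpectrum(axis_unit="ppm", lines=lines_ppm, observable="nmr")
        if grid is None:
            lo = min(p for p, _ in lines_ppm) - 10 * kernel.fwhm
            hi = max(p for p, _ in lines_ppm) + 10 * kernel.fwhm
            grid = np.linspace(lo, hi, 4001)
        spectrum = convolve(sticks, kernel, grid)
    return NMRSpectrum(
        lines=lines_ppm,
        spectrum=spectrum,
        provenance={
            "mode": mode,
            "spectrometer_mhz": mhz,
            "intensity_convention": "raw |<f|Ix|s>|^2 (exact) / unit per spin (first order)",
            "n_spins": n,
        },
    )


def _exact_lines(nu, jmat, n, floor):
    groups = _block_states(n)
    eig = []
    for states in groups:
        H = _block_hamiltonian(states, nu, jmat, n)
        w, v = np.linalg.eigh(H)
        eig.append((states, w, v))
    lines = []
    for b in range(n):  # transitions between blocks b (fewer down spins) and b+1
        sa, wa, va = eig[b]
        sb, wb, vb = eig[b + 1]
        # basis-level Ix elements: 1/2 where states differ by one flipped spin
        X = np.zeros((len(sa), len(sb)))
        index_b = {s: k for k, s in enumerate(sb)}
        for ka, s in enumerate(sa):
            for i in range(n):
                if not (s >> i) & 1:
                    X[ka, index_b[s | (1 << i)]] = 0.5
        amp = va.T @ X @ vb
        for ia in range(len(wa)):
            for ib in range(len(wb)):
                inten = amp[ia, ib] ** 2
                if inten > floor:
                    lines.append((abs(wa[ia] - wb[ib]), float(inten)))
    lines.sort()
    return lines


def first_order_lines(system):
    """First-order multiplets: each coupling splits a line into ±J/2 halves."""
    labels = list(system.shifts_ppm)
    out = []
    for l in labels:
        lines = [(system.shifts_ppm[l] * system.spectrometer_mhz, 1.0)]
        for (a, b), j in system.couplings_hz.items():
            if l in (a, b) and j != 0.0:
                lines = [(f + s * j / 2.0, inten / 2.0)
                         for f, inten in lines for s in (+1.0, -1.0)]
        out.extend(lines)
    merged = {}
    for f, inten in out:
        merged[round(f, 9)] = merged.get(round(f, 9), 0.0) + inten
    return sorted(merged.items())


def model_deviation(table_a, table_b, subset=None):
    """Absolute per-nucleus differences between two shift/shielding tables.

    Returns a dict with ``per_nucleus`` |Δ| values, ``max`` and its
    ``argmax`` label (first label wins ties, in table-a order), and
    ``mean``.  Raises when the subset is not present in both tables or the
    table kinds differ.
    """
    if table_a.kind != table_b.kind:
        raise ContractError(
            f"table kinds differ: {table_a.kind!r} vs {table_b.kind!r}"
        )
    labels = list(subset) if subset is not None else list(table_a.entries)
    missing = [l for l in labels if l not in table_a.entries or l not in table_b.entries]
    if missing:
        raise ContractError(f"labels missing from one of the tables: {missing}")
    per = {l: abs(table_a.value(l) - table_b.value(l)) for l in labels}
    argmax = max(labels, key=lambda l: per[l])  # ties: first label, max() is stable
    return {
        "per_nucleus": per,
        "max": per[argmax],
        "argmax": argmax,
        "mean": float(np.mean(list(per.values()))),
    }
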