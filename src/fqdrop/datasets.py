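"""Bundled reference data.

``trp_nmr_table``: ensemble-averaged (200 snapshots) NMR response of
zwitterionic L-tryptophan in water computed with the two polarizable
embedding models — chemical shifts (ppm, TMS-referenced) for ¹H and ¹³C
and raw magnetic shieldings (ppm) for ¹⁵N and ¹⁷O.  These numbers are
inputs for inter-model deviation statistics, not outputs of this package.

``placeholder_water_parameters``: an illustrative FQ(Fμ) water parameter
set for examples and demos only; it is NOT a validated parametrization and
no test result depends on its values.
"""

from __future__ import annotations

from .errors import ContractError
from .fq import FQParameterSet, SiteParameters
from .nmr import ShiftTable

# nucleus -> (isotope, FQ value, FQFmu value); shifts for H/C, shieldings for N/O
_TRP_NMR = {
    "H1": ("1H", 3.7336, 3.6629),
    "H2": ("1H", 3.4384, 3.4743),
    "H3": ("1H", 4.3763, 4.3996),
    "H4": ("1H", 10.0063, 10.4016),
    "H5": ("1H", 6.0134, 6.2879),
    "H6": ("1H", 5.9277, 6.1879),
    "H7": ("1H", 6.3728, 6.7483),
    "H8": ("1H", 8.2038, 8.2446),
    "H9": ("1H", 7.6214, 7.6119),
    "H10": ("1H", 7.7782, 7.7860),
    "H11": ("1H", 8.0512, 8.1204),
    "H12": ("1H", 7.9716, 8.0644),
    "C1": ("13C", 63.9518, 63.5953),
    "C2": ("13C", 30.4370, 30.4645),
    "C3": ("13C", 176.2754, 178.5201),
    "C4": ("13C", 117.7629, 117.2523),
    "C5": ("13C", 135.2466, 136.4871),
    "C6": ("13C", 143.8707, 143.8123),
    "C7": ("13C", 132.6885, 132.6688),
    "C8": ("13C", 124.3865, 124.5879),
    "C9": ("13C", 127.0266, 126.6992),
    "C10": ("13C", 129.4505, 129.1790),
    "C11": ("13C", 121.6423, 122.0687),
    "N1": ("15N", 210.4982, 211.7675),
    "N2": ("15N", 104.0095, 101.8629),
    "O1": ("17O", 35.1612, 42.1765),
    "O2": ("17O", 48.8983, 55.5504),
}

# exchangeable N-bound protons, excluded from coupled spectra by convention
TRP_EXCHANGEABLE_PROTONS = ("H4", "H5", "H6", "H7")

_FAMILY_KIND = {
    "1H": "shift_ppm",
    "13C": "shift_ppm",
    "15N": "shielding_ppm",
    "17O": "shielding_ppm",
}


def trp_nmr_table(model, isotope):
    """Reference NMR table for one model ('fq' or 'fqmu') and isotope.

    ``isotope`` is one of ``1H``, ``13C`` (chemical shifts, ppm) or
    ``15N``, ``17O`` (shieldings, ppm).  Returns a
    :class:`~fqdrop.nmr.ShiftTable`.
    """
    col = {"fq": 1, "fqmu": 2}.get(model)
    if col is None:
        raise ContractError(f"unknown model {model!r}: expected 'fq' or 'fqmu'")
    if isotope not in _FAMILY_KIND:
        raise ContractError(f"unknown isotope {isotope!r}")
    entries = {
        label: (iso, vals[col - 1])
        for label, (iso, *vals) in _TRP_NMR.items()
        if iso == isotope
    }
    return ShiftTable(entries=entries, kind=_FAMILY_KIND[isotope], model=model)


def placeholder_water_parameters(dipoles_enabled=True,
                                 kernel_dialect="gaussian_smeared"):
    """Illustrative (non-validated) FQ(Fμ) water parameters for examples.

    Hartree-based units: χ in hartree/e, η in hartree/e², α in bohr³.
    """
    return FQParameterSet(
        types={
            "OW": SiteParameters(chi=0.19, eta=0.62, alpha=5.0),
            "HW": SiteParameters(chi=0.01, eta=0.64, alpha=1.5),
        },
        dipoles_enabled=dipoles_enabled,
        kernel_dialect=kernel_dialect,
    )


def write_parameter_yaml(path, params):
    """Write an FQParameterSet in the documented YAML mapping format."""
    import yaml

    raw = {
        key: {"chi": p.chi, "eta": p.eta, **({"alpha": p.alpha} if p.alpha else {})}
        for key, p in params.types.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
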