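import numpy as np
import pytest

from fqdrop.fq import AtomSite, FQParameterSet, SiteParameters, SolventTopology
from fqdrop.synth import gen_water_droplet

# synthetic parameters: correctness never depends on any "real" water set
SYNTH_PARAMS_FQ = FQParameterSet(
    types={
        "OW": SiteParameters(chi=0.25, eta=0.7),
        "HW": SiteParameters(chi=0.05, eta=0.9),
    },
    dipoles_enabled=False,
    kernel_dialect="bare_coulomb",
)

SYNTH_PARAMS_FQMU = FQParameterSet(
    types={
        "OW": SiteParameters(chi=0.25, eta=0.7, alpha=1.5),
        "HW": SiteParameters(chi=0.05, eta=0.9, alpha=0.4),
    },
    dipoles_enabled=True,
    kernel_dialect="bare_coulomb",
)


@pytest.fixture
def fq_params():
    return SYNTH_PARAMS_FQ


@pytest.fixture
def fqmu_params():
    return SYNTH_PARAMS_FQMU


@pytest.fixture
def smeared_params():
    return FQParameterSet(
        types=SYNTH_PARAMS_FQMU.types,
        dipoles_enabled=True,
        kernel_dialect="gaussian_smeared",
    )


@pytest.fixture
def small_droplet():
    """Three rigid waters in a 5 Å ball, deterministic."""
    return gen_water_droplet(3, radius=5.0, min_separation=2.6, seed=11)


def two_site_topology(separation_angstrom, type_key="A", molecule_ids=(0, 0),
                      charges=None):
    sites = [
        AtomSite("X", (0.0, 0.0, 0.0), molecule_ids[0], type_key),
        AtomSite("X", (separation_angstrom, 0.0, 0.0), molecule_ids[1], type_key),
    ]
    if charges is None:
        charges = {m: 0.0 for m in set(molecule_ids)}
    return SolventTopology(sites=sites, molecule_charges=charges)


def uniform_field_sources(topology, field_au):
    """Sources for a uniform external field: V = −E·r (bohr), E constant."""
    from fqdrop.fq import ExternalSources

    pos = topology.positions_bohr
    field = np.asarray(field_au, dtype=float)
    return ExternalSources(V=-pos @ field, E=np.tile(field, (topology.n_sites, 1)))
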