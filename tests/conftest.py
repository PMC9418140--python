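import pytest

from icenuc.assay_io import Apparatus, Droplet, DropletAssay


def make_assay(
    temps,
    n_censored=0,
    excluded=0,
    apparatus=Apparatus.GENERIC,
    ramp_end=-45.0,
    volume=1e-9,
    dilution=1.0,
    mass_conc=1.0,
    label="fixture",
):
    """Assemble a DropletAssay from plain freeze temperatures."""
    droplets = [Droplet(f"d{i}", t) for i, t in enumerate(temps, start=1)]
    n = len(droplets)
    droplets += [Droplet(f"c{i}", None) for i in range(1, n_censored + 1)]
    droplets += [
        Droplet(f"x{i}", -20.0, excluded=True) for i in range(1, excluded + 1)
    ]
    return DropletAssay(
        assay_id="fixture",
        droplets=tuple(droplets),
        apparatus=apparatus,
        droplet_volume=volume,
        ramp_end_temp=ramp_end,
        dilution_factor=dilution,
        cell_mass_concentration=mass_conc,
        sample_label=label,
    )


@pytest.fixture
def four_droplet_assay():
    return make_assay([-6.0, -8.0, -10.0, -12.0])
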