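"""Shared fixtures: expensive experiments are run once per session."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

from myodisarray import (VirtualSampleSpec, analyze_sample, default_delta_f,
                         disarray_map, fit_lognormal, make_shell_filter,
                         multiresolution_table, generate_sample,
                         run_validation)
from myodisarray.orientation import OrientationRecord, VectorField

#: reduced virtual-strip extent (Y, X, Z um) used throughout the suite;
#: a quarter of the full 1300 x 400 x 280 um strip in each lateral axis
REDUCED_EXTENT = (650.0, 200.0, 140.0)


def make_field(directions: np.ndarray, grid_shape, reliable=None,
               sratio_norm: float = 0.5) -> VectorField:
    """Assemble a VectorField from an array of [vz, vy, vx] directions."""
    directions = np.asarray(directions, dtype=float).reshape(*grid_shape, 3)
    if reliable is None:
        reliable = np.ones(grid_shape, dtype=bool)
    records = np.empty(grid_shape, dtype=object)
    for idx in np.ndindex(tuple(grid_shape)):
        d = directions[idx]
        n = np.linalg.norm(d)
        records[idx] = OrientationRecord(
            index=idx, center_um=tuple(16.0 * (i + 0.5) for i in idx),
            direction=d / n if n else d, frequency=1 / 1.8, period=1.8,
            sratio_raw=sratio_norm, sratio_norm=sratio_norm,
            is_tissue=True, is_reliable=bool(reliable[idx]))
    return VectorField(records)


@pytest.fixture(scope="session")
def shell():
    return make_shell_filter((36, 36, 36), default_delta_f())


@pytest.fixture(scope="session")
def validation_report():
    """13 x 13 rotation grid, 20 clean phantom chunks per cell."""
    return run_validation(n_chunks=20, seed=11)


@pytest.fixture(scope="session")
def virtual_study():
    """Virtual strips at dispersions 0/5/10/20 deg, analyzed end to end."""
    results = {}
    for i, sigma in enumerate((0, 5, 10, 20)):
        spec = VirtualSampleSpec(sample_extent_um=REDUCED_EXTENT,
                                 sigma_theta_deg=float(sigma),
                                 sigma_phi_deg=float(sigma),
                                 seed=7 + 1000 * i)
        volume, truth = generate_sample(spec)
        field = analyze_sample(volume)
        results[sigma] = SimpleNamespace(
            spec=spec, volume=volume, truth=truth, field=field,
            table=multiresolution_table(field).set_index("m"))
    return results


@pytest.fixture(scope="session")
def lognormal_p_values(virtual_study):
    """D'Agostino-Pearson p-values on ln d at the 64-um scale for three
    replicate virtual samples per dispersion (the fixture sample plus two
    fresh seeds). Log-normality of the LDD is an approximate property, so
    it is assessed over replicates rather than a single draw."""
    out = {}
    for sigma in (5, 20):
        study = virtual_study[sigma]
        ps = [fit_lognormal(disarray_map(study.field, 4).valid_d()).p_value]
        for offset in (11, 22):
            spec = dataclasses.replace(study.spec,
                                       seed=study.spec.seed + offset)
            volume, _ = generate_sample(spec)
            field = analyze_sample(volume)
            ps.append(fit_lognormal(
                disarray_map(field, 4).valid_d()).p_value)
        out[sigma] = ps
    return out
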