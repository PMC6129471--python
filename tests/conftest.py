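"""Shared fixtures: the synthetic system is built once per session."""

import numpy as np
import pytest

import lhdock as L


@pytest.fixture(scope="session")
def spec():
    return L.FixtureSpec()


@pytest.fixture(scope="session")
def nuc(spec):
    return L.build_ideal_nucleosome(spec)


@pytest.fixture(scope="session")
def lh(spec, nuc):
    return L.build_toy_lh(spec, nuc)


@pytest.fixture(scope="session")
def sites(nuc):
    return L.enumerate_groove_sites(nuc)


@pytest.fixture(scope="session")
def exclusion(nuc):
    return L.build_exclusion_grid(nuc)


@pytest.fixture(scope="session")
def nuc_grid(nuc):
    """Coarse (2 Å) potential grid of the nucleosome, shared by docking tests."""
    return L.debye_huckel_grid(nuc.solute, spacing=2.0, padding=25.0)


@pytest.fixture(scope="session")
def lh_charges(lh):
    mask = np.abs(lh.solute.charges) > 1e-6
    return L.EffectiveChargeSet(
        lh.solute.reference_positions[mask],
        lh.solute.charges[mask],
        lh.solute.radii[mask],
    )


@pytest.fixture(scope="session")
def field(nuc_grid, lh_charges, exclusion):
    return L.DockingField(nuc_grid, lh_charges, exclusion)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
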