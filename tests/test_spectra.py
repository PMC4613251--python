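"""Mode moments, sum rules, chirality behavior, and Lorentzian spectra."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dipolecd.chromophore import PolarizableUnitSet
from dipolecd.core import assemble, full_solve, reduce_dispersive, solve_modes
from dipolecd.errors import DipoleCDError
from dipolecd.spectra import (
    compute_spectra, extinction_from_full_solve, mirror_image, mode_moments,
    read_spectrum_csv, wavelength_to_wavenumber, write_spectrum,
)

from conftest import make_chromophore, random_unit_set, rigid_transform


def _modes_and_strengths(units, origin=None, convention="scaled"):
    blocks = assemble(units)
    modes = solve_modes(reduce_dispersive(blocks), blocks.D)
    return blocks, modes, mode_moments(modes, units, origin=origin,
                                       convention=convention)


# --- moments and sum rules --------------------------------------------------


def test_single_oscillator_has_zero_rotational_strength():
    units = PolarizableUnitSet(p=2)
    units.chromophores.append(make_chromophore([1.0, 2.0, 3.0], [0, 1, 1]))
    _, _, ms = _modes_and_strengths(units)
    assert ms.R_k[0] == 0.0


def test_coplanar_system_has_zero_rotational_strengths():
    # positions and polarizations all in the xy-plane: mu in-plane, m normal
    rng = np.random.default_rng(2)
    units = PolarizableUnitSet(p=5)
    placed = []
    while len(placed) < 4:
        c = rng.uniform(0, 12, size=2)
        if all(np.linalg.norm(c - p) > 3.0 for p in placed):
            placed.append(c)
    for c in placed:
        ang = rng.uniform(0, 2 * np.pi)
        units.chromophores.append(
            make_chromophore([c[0], c[1], 0.0], [np.cos(ang), np.sin(ang), 0],
                             nu0=rng.uniform(45000, 55000)))
    _, _, ms = _modes_and_strengths(units)
    assert np.abs(ms.R_k).max() < 1e-10 * np.abs(ms.D_k).max()


@pytest.mark.parametrize("seed", range(4))
@pytest.mark.parametrize("convention", ["scaled", "as-printed"])
def test_conservation_sum_rules(seed, convention):
    rng = np.random.default_rng(100 + seed)
    units = random_unit_set(rng, n_disp=6, n_iso=4, with_static=(seed % 2 == 0))
    blocks, modes, ms = _modes_and_strengths(units, convention=convention)
    if convention == "scaled":
        assert np.isclose(ms.D_k.sum(), blocks.D.sum(), rtol=1e-8)
    else:
        assert np.isclose(ms.D_k.sum(), units.q, rtol=1e-8)
    assert abs(ms.R_k.sum()) < 1e-8 * max(np.abs(ms.R_k).sum(), 1e-10)


def test_rotational_strengths_origin_independent():
    rng = np.random.default_rng(9)
    units = random_unit_set(rng, n_disp=6, n_iso=2)
    _, _, ms0 = _modes_and_strengths(units, origin=np.zeros(3))
    _, _, ms1 = _modes_and_strengths(units, origin=np.array([25.0, -13.0, 7.0]))
    assert np.allclose(ms0.R_k, ms1.R_k,
                       atol=1e-10 * max(np.abs(ms0.R_k).max(), 1.0))
    assert np.allclose(ms0.D_k, ms1.D_k, rtol=1e-12)


def test_rotational_strengths_invariant_under_rigid_motion():
    rng = np.random.default_rng(13)
    units = random_unit_set(rng, n_disp=5, n_iso=3)
    R = Rotation.random(random_state=rng).as_matrix()
    moved = rigid_transform(units, R, rng.normal(size=3) * 8)
    _, _, ms0 = _modes_and_strengths(units)
    _, _, ms1 = _modes_and_strengths(moved)
    assert np.allclose(ms0.D_k, ms1.D_k, rtol=1e-8)
    assert np.allclose(ms0.R_k, ms1.R_k,
                       rtol=1e-6, atol=1e-8 * np.abs(ms0.R_k).max())


# --- mirror image -----------------------------------------------------------


def test_double_reflection_is_identity():
    rng = np.random.default_rng(19)
    units = random_unit_set(rng, n_disp=4, n_iso=2, with_static=True)
    back = mirror_image(mirror_image(units, normal=(1, 2, 3), point=(1, 0, 0)),
                        normal=(1, 2, 3), point=(1, 0, 0))
    for c0, c1 in zip(units.chromophores, back.chromophores):
        assert np.allclose(c0.position, c1.position, atol=1e-12)
        assert np.allclose(c0.u, c1.u, atol=1e-12)
        assert np.allclose(c0.alpha_static, c1.alpha_static, atol=1e-12)
    for a0, a1 in zip(units.isotropics, back.isotropics):
        assert np.allclose(a0.position, a1.position, atol=1e-12)


def test_enantiomer_negates_rotational_strengths_only():
    rng = np.random.default_rng(29)
    units = random_unit_set(rng, n_disp=6, n_iso=3, with_static=True)
    _, modes0, ms0 = _modes_and_strengths(units)
    mirrored = mirror_image(units, normal=(0.3, -1.0, 0.7))
    _, modes1, ms1 = _modes_and_strengths(mirrored)
    assert np.allclose(modes0.nu_k_sq, modes1.nu_k_sq, rtol=1e-10)
    assert np.allclose(ms0.D_k, ms1.D_k, rtol=1e-8)
    assert np.allclose(ms0.R_k, -ms1.R_k,
                       rtol=1e-8, atol=1e-10 * np.abs(ms0.R_k).max())


def test_enantiomer_spectra_flip_cd_and_preserve_absorption():
    rng = np.random.default_rng(43)
    units = random_unit_set(rng, n_disp=5, n_iso=2)
    _, modes0, ms0 = _modes_and_strengths(units)
    sp0 = compute_spectra(ms0, modes0, gamma=5000.0, p=units.p)
    mirrored = mirror_image(units)
    _, modes1, ms1 = _modes_and_strengths(mirrored)
    sp1 = compute_spectra(ms1, modes1, gamma=5000.0, p=units.p)
    assert np.allclose(sp0.epsilon, sp1.epsilon, rtol=1e-8)
    assert np.allclose(sp0.delta_epsilon, -sp1.delta_epsilon,
                       rtol=1e-8, atol=1e-12 * np.abs(sp0.delta_epsilon).max())


# --- spectra ----------------------------------------------------------------


def test_achiral_system_gives_identically_zero_cd():
    units = PolarizableUnitSet(p=3)
    units.chromophores.append(make_chromophore([0, 0, 0], [1, 0, 0]))
    units.chromophores.append(make_chromophore([4, 0, 0], [0, 1, 0]))
    _, modes, ms = _modes_and_strengths(units)
    sp = compute_spectra(ms, modes, gamma=5000.0, p=units.p)
    assert np.allclose(sp.delta_epsilon, 0.0, atol=1e-20)
    assert np.all(sp.epsilon >= 0.0)


def test_single_mode_peaks_at_its_wavelength():
    units = PolarizableUnitSet(p=2)
    units.chromophores.append(make_chromophore([0, 0, 0], [0, 0, 1],
                                               nu0=50000.0, D=1.5e9))
    _, modes, ms = _modes_and_strengths(units)
    sp = compute_spectra(ms, modes, gamma=6000.0, p=2)
    lam_peak = sp.wavelength_nm[np.argmax(sp.epsilon)]
    assert abs(lam_peak - 1e7 / 50000.0) <= 1.0  # within one grid step


def test_epsilon_nonnegative_everywhere():
    rng = np.random.default_rng(53)
    for seed in range(5):
        units = random_unit_set(np.random.default_rng(seed), n_disp=6, n_iso=3)
        _, modes, ms = _modes_and_strengths(units)
        sp = compute_spectra(ms, modes, gamma=4000.0, p=units.p)
        assert np.all(sp.epsilon >= 0.0)


def test_mode_sum_matches_full_complex_solve_mixed_system():
    rng = np.random.default_rng(61)
    units = random_unit_set(rng, n_disp=7, n_iso=4, with_static=True)
    _, modes, ms = _modes_and_strengths(units)
    sp = compute_spectra(ms, modes, gamma=5500.0, p=units.p)
    nu = wavelength_to_wavenumber(sp.wavelength_nm)
    fs = full_solve(units, nu, gamma=5500.0)
    eps_direct = extinction_from_full_solve(fs.trace_dispersive, nu, units.p)
    assert np.max(np.abs(eps_direct - sp.epsilon) / sp.epsilon) < 1e-6


def test_wavelength_wavenumber_conversion():
    assert wavelength_to_wavenumber(200.0) == 50000.0
    assert wavelength_to_wavenumber(100.0) == 100000.0
    lam = np.linspace(150.0, 260.0, 23)
    assert np.allclose(1e7 / wavelength_to_wavenumber(lam), lam, rtol=1e-14)
    with pytest.raises(DipoleCDError):
        wavelength_to_wavenumber(0.0)


def test_spectrum_writer_roundtrip(tmp_path):
    rng = np.random.default_rng(71)
    units = random_unit_set(rng, n_disp=4)
    _, modes, ms = _modes_and_strengths(units)
    sp = compute_spectra(ms, modes, gamma=5000.0, p=units.p,
                         metadata={"note": "test"})
    path = tmp_path / "spec.csv"
    write_spectrum(sp, path)
    again = read_spectrum_csv(path)
    assert np.allclose(again.wavelength_nm, sp.wavelength_nm)
    assert np.allclose(again.epsilon, sp.epsilon, rtol=1e-6)
    assert np.allclose(again.delta_epsilon, sp.delta_epsilon, rtol=1e-6)
    assert again.metadata["note"] == "test"


def test_spectrum_requires_positive_gamma_and_two_residues():
    rng = np.random.default_rng(73)
    units = random_unit_set(rng, n_disp=3)
    _, modes, ms = _modes_and_strengths(units)
    with pytest.raises(DipoleCDError):
        compute_spectra(ms, modes, gamma=0.0, p=units.p)
    with pytest.raises(DipoleCDError):
        compute_spectra(ms, modes, gamma=5000.0, p=1)
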