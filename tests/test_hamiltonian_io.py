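"""Hamiltonian/geometry I/O, synthetic fixtures and PES generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sqd_binder import (
    ActiveSpaceSpec,
    EngineUnavailableError,
    FormatError,
    Geometry,
    GeometryError,
    cas_dimension,
    casci_energy,
    pes_geometries,
    prepare_active_space,
    random_hamiltonian,
    read_fcidump,
    read_xyz,
    translate_monomer,
    write_fcidump,
    write_xyz,
)


class TestFcidump:
    def test_single_orbital_fields(self, tmp_path):
        path = tmp_path / "one.fcidump"
        path.write_text(
            "&FCI NORB=1,NELEC=2,MS2=0,\n ORBSYM=1,\n ISYM=1,\n/\n"
            " 0.5 1 1 1 1\n-1.0 1 1 0 0\n 0.2 0 0 0 0\n"
        )
        ham = read_fcidump(path)
        assert ham.m == 1 and ham.n_alpha == 1 and ham.n_beta == 1
        assert ham.h[0, 0] == -1.0
        assert ham.eri[0, 0, 0, 0] == 0.5
        assert ham.e0 == 0.2

    @pytest.mark.parametrize("m,na,nb", [(1, 1, 1), (2, 1, 1), (4, 2, 2), (5, 3, 2)])
    def test_round_trip(self, tmp_path, m, na, nb):
        ham = random_hamiltonian(m, na, nb, seed=m * 10 + na)
        path = tmp_path / "rt.fcidump"
        write_fcidump(ham, path)
        back = read_fcidump(path)
        assert back.m == ham.m
        assert (back.n_alpha, back.n_beta) == (ham.n_alpha, ham.n_beta)
        assert abs(back.e0 - ham.e0) < 1e-12
        assert np.abs(back.h - ham.h).max() < 1e-12
        assert np.abs(back.eri - ham.eri).max() < 1e-12

    def test_external_dialect(self, tmp_path):
        """A dump with Fortran D-exponents, non-canonical index order and
        loose spacing must reproduce the same CASCI ground energy."""
        ham = random_hamiltonian(2, 1, 1, seed=3)
        path = tmp_path / "ext.fcidump"
        lines = ["&FCI  NORB= 2, NELEC=2, MS2=0,", "  ORBSYM=1,1,", "  ISYM=1,", " /"]

        def fmt(v):
            return f"{v:.14E}".replace("E", "D")

        # emit eri with deliberately non-canonical representatives
        seen = set()
        for p in range(2):
            for r in range(2):
                for q in range(2):
                    for s in range(2):
                        key = frozenset(
                            [(p, r, q, s), (r, p, s, q), (q, s, p, r), (s, q, r, p)]
                        )
                        if key in seen:
                            continue
                        seen.add(key)
                        lines.append(
                            f"  {fmt(ham.eri[p, r, q, s])}   {q+1} {s+1} {p+1} {r+1}"
                        )
        for p in range(2):
            for r in range(p + 1):
                lines.append(f"  {fmt(ham.h[p, r])}   {r+1} {p+1} 0 0")
        lines.append(f"  {fmt(ham.e0)}   0 0 0 0")
        path.write_text("\n".join(lines) + "\n")
        back = read_fcidump(path)
        e_ref = casci_energy(ham, compute_variance=False).energy
        e_back = casci_energy(back, compute_variance=False).energy
        assert abs(e_back - e_ref) < 1e-10

    def test_record_count_bound(self, tmp_path):
        """At most one record per 8-fold symmetry class is emitted.

        The class count equals npair*(npair+1)/2 with npair = M(M+1)/2
        (Burnside count (M^4 + 2M^3 + 3M^2 + 2M)/8, verified by direct
        enumeration below), plus M(M+1)/2 one-electron records plus E0.
        """
        m = 4
        # independent enumeration of the orbit count
        orbits = set()
        for idx in np.ndindex(m, m, m, m):
            p, r, q, s = idx
            orbit = frozenset(
                [
                    (p, r, q, s), (r, p, q, s), (p, r, s, q), (r, p, s, q),
                    (q, s, p, r), (s, q, p, r), (q, s, r, p), (s, q, r, p),
                ]
            )
            orbits.add(orbit)
        npair = m * (m + 1) // 2
        assert len(orbits) == npair * (npair + 1) // 2
        ham = random_hamiltonian(m, 2, 2, seed=1)
        path = tmp_path / "count.fcidump"
        write_fcidump(ham, path)
        body = path.read_text().split("/\n", 1)[1]
        records = [ln for ln in body.splitlines() if ln.strip()]
        assert len(records) <= len(orbits) + npair + 1

    @pytest.mark.parametrize(
        "text",
        [
            "no header at all\n 1.0 1 1 1 1\n",
            "&FCI NORB=2,NELEC=2,MS2=0,/\n 1.0 3 1 1 1\n",
            "&FCI NORB=2,NELEC=2,MS2=0,/\n 1.0 1 1\n",
            "&FCI NELEC=2,MS2=0,/\n 1.0 1 1 1 1\n",
        ],
    )
    def test_malformed_raises(self, tmp_path, text):
        path = tmp_path / "bad.fcidump"
        path.write_text(text)
        with pytest.raises(FormatError):
            read_fcidump(path)

    def test_unwritable_path(self, ham3):
        with pytest.raises(OSError):
            write_fcidump(ham3, "/nonexistent-dir/x.fcidump")


class TestRandomHamiltonian:
    def test_deterministic(self):
        a = random_hamiltonian(4, 2, 2, seed=7)
        b = random_hamiltonian(4, 2, 2, seed=7)
        assert np.array_equal(a.h, b.h) and np.array_equal(a.eri, b.eri)
        assert a.e0 == b.e0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_integral_symmetries(self, seed):
        ham = random_hamiltonian(3, 2, 1, seed=seed)
        ham.validate_symmetry(tol=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            random_hamiltonian(0, 0, 0, seed=1)
        with pytest.raises(ValueError):
            random_hamiltonian(2, 3, 1, seed=1)


class TestGeometry:
    def test_xyz_round_trip(self, tmp_path, water_dimer_geometry):
        path = tmp_path / "g.xyz"
        write_xyz(water_dimer_geometry, path)
        back = read_xyz(path)
        assert back.metadata == water_dimer_geometry.metadata
        assert np.abs(back.coords - water_dimer_geometry.coords).max() < 1e-9
        assert [a[0] for a in back.atoms] == [
            a[0] for a in water_dimer_geometry.atoms
        ]

    def test_translate_identity(self, water_dimer_geometry):
        g = water_dimer_geometry
        current = g.distance(0, 3)
        out = translate_monomer(g, {3, 4, 5}, 0, 3, current)
        assert np.abs(out.coords - g.coords).max() < 1e-12

    def test_translate_to_unbound_distance(self, water_dimer_geometry):
        out = translate_monomer(water_dimer_geometry, {3, 4, 5}, 0, 3, 48.0)
        assert abs(out.distance(0, 3) - 48.0) < 1e-10

    @given(target=st.floats(0.5, 60.0))
    @settings(max_examples=30, deadline=None)
    def test_translate_preserves_monomers(self, water_dimer_geometry, target):
        g = water_dimer_geometry
        out = translate_monomer(g, {3, 4, 5}, 0, 3, target)
        for mono in ((0, 1, 2), (3, 4, 5)):
            for i in mono:
                for j in mono:
                    assert abs(out.distance(i, j) - g.distance(i, j)) < 1e-10

    def test_scan_grid_matches_targets(self, water_dimer_geometry):
        targets = [round(1.4 + 0.1 * i, 3) for i in range(22)]  # 1.4 .. 3.5
        series, unbound = pes_geometries(
            water_dimer_geometry, {3, 4, 5}, 0, 3, targets
        )
        dists = [g.distance(0, 3) for _, g in series]
        assert np.abs(np.array(dists) - np.array(targets)).max() < 1e-10
        assert all(b > a for a, b in zip(dists, dists[1:]))
        assert abs(unbound.distance(0, 3) - 48.0) < 1e-10

    def test_coincident_anchors(self):
        g = Geometry([("H", 0, 0, 0), ("H", 0, 0, 0)])
        with pytest.raises(GeometryError):
            translate_monomer(g, {1}, 0, 1, 2.0)

    def test_anchor_membership(self, water_dimer_geometry):
        with pytest.raises(ValueError):
            translate_monomer(water_dimer_geometry, {3, 4, 5}, 0, 1, 2.0)
        with pytest.raises(ValueError):
            translate_monomer(water_dimer_geometry, {0, 1, 2}, 0, 3, 2.0)


class TestActiveSpace:
    def test_cas_dimension(self):
        assert cas_dimension(12, 8, 8) == math.comb(12, 8) ** 2

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ActiveSpaceSpec(["O 2s"], n_electrons=4, n_orbitals=1)
        spec = ActiveSpaceSpec(["O 2s", "O 2p", "H 1s"], 16, 12)
        assert spec.n_orbitals == 12

    def test_engine_boundary(self, water_dimer_geometry):
        try:
            import pyscf  # noqa: F401

            pytest.skip("external engine installed; boundary not exercised")
        except ImportError:
            pass
        spec = ActiveSpaceSpec(["O 2s", "O 2p", "H 1s"], 16, 12)
        with pytest.raises(EngineUnavailableError):
            prepare_active_space(water_dimer_geometry, spec, basis="aug-cc-pvqz")
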