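"""The scaled circular metric, votes, confal scoring and assignment."""

import math

import numpy as np
import pytest

from ntcana.classify import (
    ClassTableError,
    GoldenSet,
    assign_step,
    cartesian_rmsd,
    confal_parameter_score,
    confal_step_score,
    deviations,
    load_class_table,
    parameter_votes,
    step_distance,
    torsion_rmsd,
    write_class_table,
)
from ntcana.geometry import StepParameters, circular_difference
from ntcana.structure_io import AtomRecord, RawStep
from ntcana.synthetic import build_step_coordinates, sample_class_instances

from conftest import aa_torsions, random_torsions


def random_params(rng, n=1):
    out = []
    for _ in range(n):
        vec = np.concatenate([rng.uniform(0, 360, 10), rng.uniform(2, 15, 2)])
        out.append(StepParameters.from_vector(vec))
    return out[0] if n == 1 else out


class TestClassTableIO:
    def test_demo_table_round_trips(self, demo_table, tmp_path):
        path = tmp_path / "classes.csv"
        write_class_table(demo_table, path)
        loaded = load_class_table(path)
        assert loaded.names == demo_table.names
        assert loaded.scaling == 32.0

    def test_duplicate_names_rejected(self, demo_table, tmp_path):
        path = tmp_path / "dup.csv"
        write_class_table(demo_table, path)
        lines = path.read_text().splitlines()
        lines.append(lines[1])  # repeat the first data row
        path.write_text("\n".join(lines))
        with pytest.raises(ClassTableError, match="duplicate"):
            load_class_table(path)

    def test_nonpositive_spread_rejected(self, demo_table, tmp_path):
        path = tmp_path / "bad.csv"
        write_class_table(demo_table, path)
        text = path.read_text()
        header, first, rest = text.split("\n", 2)
        cells = first.split(",")
        cells[-1] = "0.0"
        path.write_text("\n".join([header, ",".join(cells), rest]))
        with pytest.raises(ClassTableError):
            load_class_table(path)


class TestStepDistance:
    def test_identity(self, rng):
        p = random_params(rng)
        assert step_distance(p, p) == 0.0

    def test_single_distance_component_scaled(self, rng):
        p = random_params(rng)
        q = StepParameters.from_vector(
            np.concatenate([p.angles(), [p.nn + 0.5, p.cc]])
        )
        assert step_distance(p, q, scaling=32.0) == pytest.approx(16.0)

    def test_matches_componentwise_oracle(self, rng):
        for _ in range(1000):
            a, b = random_params(rng, 2)
            brute = math.sqrt(
                sum(
                    circular_difference(x, y) ** 2
                    for x, y in zip(a.angles(), b.angles())
                )
                + sum((32.0 * (x - y)) ** 2 for x, y in zip(a.distances(), b.distances()))
            )
            assert step_distance(a, b, 32.0) == pytest.approx(brute, abs=1e-9)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(300):
            a, b, c = random_params(rng, 3)
            dab = step_distance(a, b)
            assert dab == pytest.approx(step_distance(b, a), abs=1e-9)
            assert dab <= step_distance(a, c) + step_distance(c, b) + 1e-9


class TestVotes:
    def test_centroid_gets_all_twelve(self, demo_table):
        c = demo_table.classes[0]
        assert parameter_votes(c.means, c) == 12

    def test_single_violated_window(self, demo_table):
        c = demo_table.classes[0]
        vec = c.means.vector()
        vec[3] = (vec[3] + 120.0) % 360.0  # far beyond 3*spread and floor
        assert parameter_votes(StepParameters.from_vector(vec), c) == 11

    def test_matches_componentwise_oracle(self, demo_table, rng):
        c = demo_table.classes[2]
        windows = np.maximum(3.0 * np.asarray(c.spreads), [15.0] * 10 + [0.5] * 2)
        for _ in range(300):
            s = random_params(rng)
            brute = int(np.sum(deviations(s, c.means) <= windows))
            assert parameter_votes(s, c) == brute

    def test_widening_spreads_never_loses_votes(self, demo_table, rng):
        base = demo_table.classes[1]
        wide = type(base)(
            name=base.name, cana=base.cana, means=base.means,
            spreads=tuple(2.0 * s for s in base.spreads),
        )
        for _ in range(200):
            s = random_params(rng)
            assert parameter_votes(s, wide) >= parameter_votes(s, base)


class TestConfal:
    def test_gaussian_kernel_reference_points(self):
        assert confal_parameter_score(0.0, 5.0) == 100.0
        assert confal_parameter_score(5.0, 5.0) == pytest.approx(100 * math.exp(-0.5))
        assert confal_parameter_score(50.0, 5.0) == 1e-4  # clamped

    def test_harmonic_mean_two_component_example(self):
        assert confal_step_score([100.0, 25.0]) == pytest.approx(40.0)

    def test_harmonic_never_exceeds_arithmetic(self, rng):
        for _ in range(500):
            comps = rng.uniform(1e-4, 100.0, 12)
            assert confal_step_score(comps) <= comps.mean() + 1e-12

    def test_monotone_in_any_single_deviation(self, demo_table):
        c = demo_table.classes[0]
        last = None
        for dev in np.linspace(0, 40, 15):
            vec = c.means.vector()
            vec[5] = (vec[5] + dev) % 360.0
            s = StepParameters.from_vector(vec)
            comps = [
                confal_parameter_score(d, sp)
                for d, sp in zip(deviations(s, c.means), c.spreads)
            ]
            score = confal_step_score(comps)
            if last is not None:
                assert score <= last + 1e-9
            last = score


class TestRmsd:
    def test_torsion_rmsd_constant_offset(self, rng):
        a = random_params(rng)
        vec = a.vector().copy()
        vec[:10] = (vec[:10] + 10.0) % 360.0
        b = StepParameters.from_vector(vec)
        assert torsion_rmsd(a, b) == pytest.approx(10.0)
        assert torsion_rmsd(a, a) == 0.0

    def test_torsion_rmsd_matches_brute_force(self, rng):
        for _ in range(1000):
            a, b = random_params(rng, 2)
            brute = math.sqrt(
                np.mean(
                    [circular_difference(x, y) ** 2
                     for x, y in zip(a.angles(), b.angles())]
                )
            )
            assert torsion_rmsd(a, b) == pytest.approx(brute, abs=1e-9)

    def test_cartesian_rmsd_removes_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        step = build_step_coordinates(aa_torsions())
        rot = Rotation.random(random_state=11).as_matrix()
        moved = RawStep(
            step_id="m", first=step.first, second=step.second,
            atoms18=[
                AtomRecord(a.name, a.element,
                           tuple(rot @ np.array(a.position) + [3.0, -7.0, 1.0]))
                for a in step.atoms18
            ],
        )
        assert cartesian_rmsd(step, step) < 1e-12
        assert cartesian_rmsd(step, moved) < 1e-9

    def test_cartesian_rmsd_matches_quaternion_oracle(self, rng):
        step = build_step_coordinates(aa_torsions())
        displaced_atoms = list(step.atoms18)
        a0 = displaced_atoms[0]
        displaced_atoms[0] = AtomRecord(
            a0.name, a0.element,
            (a0.position[0] + 1.8, a0.position[1], a0.position[2]),
        )
        other = RawStep(step_id="d", first=step.first, second=step.second,
                        atoms18=displaced_atoms)
        ours = cartesian_rmsd(step, other)
        assert ours > 0
        assert ours == pytest.approx(_quaternion_rmsd(step, other), abs=1e-6)

    def test_mismatched_atom_lists_rejected(self):
        step = build_step_coordinates(aa_torsions())
        short = RawStep(step_id="s", first=step.first, second=step.second,
                        atoms18=step.atoms18[:17])
        with pytest.raises(ValueError):
            cartesian_rmsd(step, short)


def _quaternion_rmsd(a, b):
    """Independent superposition rmsd via Horn's quaternion method."""
    pa = np.array([at.position for at in a.atoms18], dtype=float)
    pb = np.array([at.position for at in b.atoms18], dtype=float)
    pa -= pa.mean(axis=0)
    pb -= pb.mean(axis=0)
    m = pa.T @ pb
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(pa ** 2) + np.sum(pb ** 2) - 2.0 * lam) / len(pa)
    return math.sqrt(max(msd, 0.0))


class TestAssignment:
    def test_centroid_assigns_perfectly(self, demo_table):
        for c in demo_table.classes:
            r = assign_step(c.means, demo_table)
            assert r.ntc == c.name and r.cana == c.cana
            assert r.votes == 12
            assert r.confal == 100.0
            assert r.distance == 0.0

    def test_far_from_everything_is_nant(self, demo_table, demo_golden):
        vec = np.concatenate([np.full(10, 0.0), [20.0, 20.0]])
        # pick angles 90 deg away from every class mean per parameter
        vec[:10] = [
            (demo_table.classes[0].means.angles()[i] + 180.0) % 360.0
            for i in range(10)
        ]
        r = assign_step(StepParameters.from_vector(vec), demo_table, demo_golden)
        assert r.ntc == "NANT" and r.cana == "NAN"
        assert r.nearest_class in demo_table.names
        assert r.distance > 0 and r.torsion_rmsd > 0

    def test_low_noise_samples_recover_their_class(self, demo_table, demo_golden):
        hits = total = 0
        for i, c in enumerate(demo_table.classes):
            for s in sample_class_instances(c, 500, noise_scale=0.25, seed=900 + i):
                total += 1
                hits += assign_step(s, demo_table, demo_golden).ntc == c.name
        assert hits / total >= 0.99

    def test_pure_noise_goes_nant(self, demo_table, demo_golden, rng):
        nant = 0
        n = 400
        for _ in range(n):
            s = random_params(rng)
            nant += assign_step(s, demo_table, demo_golden).ntc == "NANT"
        assert nant / n > 0.99

    def test_centroid_mode_picks_nearest_candidate(self, demo_table, rng):
        # at a class centroid with golden absent, winner's centroid
        # distance must not exceed any other class's
        for c in demo_table.classes:
            for s in sample_class_instances(c, 20, noise_scale=0.25, seed=77):
                r = assign_step(s, demo_table)
                if r.ntc == "NANT":
                    continue
                d_win = step_distance(s, demo_table[r.ntc].means, demo_table.scaling)
                for other in demo_table.classes:
                    assert d_win <= step_distance(
                        s, other.means, demo_table.scaling
                    ) + 1e-9 or parameter_votes(
                        s, other, demo_table.tolerance_multiplier
                    ) < demo_table.vote_quorum

    def test_empty_table_rejected(self, rng):
        from ntcana.classify import ClassTable

        with pytest.raises(ClassTableError):
            assign_step(random_params(rng), ClassTable(classes=[]))

    def test_idealized_cartesian_rmsd_diagnostic(self, demo_table, demo_golden):
        c = demo_table.classes[0]
        s = sample_class_instances(c, 1, noise_scale=0.25, seed=5)[0]
        r = assign_step(s, demo_table, demo_golden, compute_cartesian_rmsd=True)
        assert r.cartesian_rmsd is not None and r.cartesian_rmsd >= 0.0

    def test_golden_set_must_match_table(self, demo_table, rng):
        bad = GoldenSet([(random_params(rng), "XX99")])
        with pytest.raises(ClassTableError):
            assign_step(random_params(rng), demo_table, bad)
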