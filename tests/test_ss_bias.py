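"""Beta-strand bias statistics and relative solvent accessibility."""

from itertools import combinations

import numpy as np
import pytest

from hdclms import SyntheticConfig, linkable_pairs, make_structure
from hdclms.ss_bias import (MAX_ASA, SSAnnotation, assign_ss, atom_sasa,
                            beta_residue_fraction, ca_sphere_radius,
                            collapse_dssp, compute_rsa,
                            expected_pair_beta_fraction, kr_content_by_class,
                            observed_pair_beta_fraction, read_ss_table,
                            rsa_summary)
from hdclms.structure import Residue, StructureModel

from conftest import make_chain


def brute_expected_fraction(labels, mode):
    pairs = list(combinations(range(1, len(labels) + 1), 2))
    count, _ = observed_pair_beta_fraction(pairs, labels, mode)
    return 100.0 * count / len(pairs)


class TestAnnotations:
    def test_dssp_collapse(self):
        assert [collapse_dssp(c) for c in "EBHGITS-"] == \
            ["E", "E", "H", "H", "H", "C", "C", "C"]

    def test_read_table_round_trip(self, tmp_path):
        from hdclms.synthetic import write_ss_table
        path = tmp_path / "ss.tsv"
        write_ss_table("EEHHCC", path)
        assert read_ss_table(path).labels == "EEHHCC"

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            SSAnnotation("EXH")

    def test_builtin_assigner_recovers_generated_fold(self):
        cfg = SyntheticConfig(n_residues=80, fold_spec="beta-sandwich",
                              unresolved_fraction=0.0, seed=21)
        model, true_ss, _ = make_structure(cfg)
        got = assign_ss(model)
        true_frac = 100 * true_ss.count("E") / len(true_ss)
        got_frac = 100 * got.labels.count("E") / len(got.labels)
        assert abs(got_frac - true_frac) <= 10

    def test_builtin_assigner_identifies_helix(self):
        cfg = SyntheticConfig(n_residues=60, fold_spec="helix-bundle",
                              unresolved_fraction=0.0, seed=22)
        model, true_ss, _ = make_structure(cfg)
        got = assign_ss(model).labels
        helix_true = [i for i, c in enumerate(true_ss) if c == "H"]
        agree = np.mean([got[i] == "H" for i in helix_true])
        assert agree > 0.8


class TestBetaFractions:
    def test_no_strands(self):
        assert beta_residue_fraction("H" * 30) == 0

    def test_paper_arithmetic_54_percent(self):
        assert beta_residue_fraction("E" * 27 + "C" * 23) == 54

    def test_observed_at_least_one_64_percent(self):
        labels = "E" * 100 + "C" * 165
        pairs = [(1, i) for i in range(2, 172)] + \
                [(101, 101 + i) for i in range(1, 96)]
        count, pct = observed_pair_beta_fraction(pairs, labels)
        assert (count, pct) == (170, 64)

    def test_both_mode_is_subset(self):
        rng = np.random.default_rng(0)
        labels = "".join(rng.choice(list("EHC"), 50))
        pairs = [tuple(sorted(rng.choice(50, 2, replace=False) + 1))
                 for _ in range(100)]
        c_any, _ = observed_pair_beta_fraction(pairs, labels, "at_least_one")
        c_both, _ = observed_pair_beta_fraction(pairs, labels, "both")
        assert c_both <= c_any

    def test_one_coil_end_never_counts_in_both_mode(self):
        labels = "EC" * 10
        pairs = [(1, 2), (3, 4)]
        assert observed_pair_beta_fraction(pairs, labels, "both") == (0, 0)


class TestExpectedFraction:
    def test_all_beta_is_certain(self):
        assert expected_pair_beta_fraction("E" * 10) == pytest.approx(100.0)

    def test_54_percent_beta_gives_about_79(self):
        labels = ("E" * 216 + "C" * 184)  # b/n = 0.54, n = 400
        got = expected_pair_beta_fraction(labels)
        assert got == pytest.approx(100 * (1 - 0.46 ** 2), abs=0.15)
        assert got == pytest.approx(brute_expected_fraction(labels, "at_least_one"))

    @pytest.mark.parametrize("n", [2, 3, 5, 10, 25, 60, 100])
    def test_closed_form_matches_enumeration_all_b(self, n):
        for b in range(0, n + 1, max(1, n // 7)):
            labels = "E" * b + "C" * (n - b)
            for mode in ("at_least_one", "both"):
                assert expected_pair_beta_fraction(labels, mode) == \
                    pytest.approx(brute_expected_fraction(labels, mode))

    def test_linkable_universe_enumeration(self):
        seq = "KACEDEFGHI"
        labels = "EECCHHCCEE"
        pool = linkable_pairs(seq)
        want = 100.0 * sum(1 for i, j in pool
                           if labels[i - 1] == "E" or labels[j - 1] == "E") / len(pool)
        got = expected_pair_beta_fraction(labels, universe="linkable_pairs",
                                          sequence=seq)
        assert got == pytest.approx(want)

    def test_uniform_links_from_linkable_pool_match_expectation(self):
        # the null model: links drawn uniformly from linkable pairs show no
        # beta bias relative to the linkable-universe expectation
        rng = np.random.default_rng(5)
        cfg = SyntheticConfig(n_residues=120, fold_spec="beta-sandwich",
                              unresolved_fraction=0.0, seed=23)
        _, ss, seq = make_structure(cfg)
        pool = linkable_pairs(seq)
        n = 2000
        draws = [pool[k] for k in rng.integers(0, len(pool), n)]
        _, obs_pct = observed_pair_beta_fraction(draws, ss)
        exp_pct = expected_pair_beta_fraction(ss, universe="linkable_pairs",
                                              sequence=seq)
        se = 100 * np.sqrt((exp_pct / 100) * (1 - exp_pct / 100) / n)
        assert abs(obs_pct - exp_pct) <= 3 * se + 0.5  # 0.5: integer rounding


class TestKRContent:
    def test_no_kr(self):
        out = kr_content_by_class("AAAA", "EHCE")
        assert (out["overall"]["percent"], out["strand"]["percent"],
                out["other"]["percent"]) == (0, 0, 0)

    def test_all_strand_kr(self):
        out = kr_content_by_class("KRKR", "EEEE")
        assert out["strand"]["percent"] == 100
        assert out["other"]["n_residues"] == 0

    def test_counts_reconstruct_overall(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACDKRSTGW"), 200))
            ss = "".join(rng.choice(list("EHC"), 200))
            out = kr_content_by_class(seq, ss)
            assert out["strand"]["kr_count"] + out["other"]["kr_count"] == \
                out["overall"]["kr_count"]
            assert out["strand"]["n_residues"] + out["other"]["n_residues"] == 200


def shell_model(center_aa="A", n_shell=120, radius=4.5):
    """A residue fully enclosed by a spherical shell of dummy residues."""
    from hdclms.ss_bias import _fibonacci_sphere
    residues = [Residue(1, center_aa, np.zeros(3))]
    for k, p in enumerate(_fibonacci_sphere(n_shell), start=2):
        residues.append(Residue(k, "A", radius * p))
    return StructureModel(residues)


class TestRSA:
    def test_isolated_residue_is_fully_exposed(self):
        for aa in "AKWG":
            model = StructureModel([Residue(1, aa, np.zeros(3))])
            rsa = compute_rsa(model)
            assert rsa[0] == pytest.approx(1.0, abs=0.15)

    def test_enclosed_residue_is_buried(self):
        rsa = compute_rsa(shell_model())
        assert rsa[0] < 0.05

    def test_dot_density_doubling_stable(self):
        cfg = SyntheticConfig(n_residues=50, unresolved_fraction=0.0, seed=24)
        model, _, _ = make_structure(cfg)
        r1 = compute_rsa(model, n_dots=960)
        r2 = compute_rsa(model, n_dots=1920)
        assert np.nanmax(np.abs(r1 - r2)) < 0.02

    def test_core_buried_below_surface(self):
        rsa = compute_rsa(shell_model())
        assert rsa[0] < np.mean(rsa[1:])

    def test_unresolved_residues_nan(self):
        model = make_chain("AKAY", unresolved={2})
        rsa = compute_rsa(model)
        assert np.isnan(rsa[1]) and not np.isnan(rsa[0])

    def test_matches_independent_shrake_rupley(self):
        # cross-check the dot-sampling surface against biotite on the same
        # spheres (same probe, same radii)
        import biotite.structure as struc
        rng = np.random.default_rng(9)
        centers = rng.uniform(0, 12, size=(30, 3))
        radii = rng.uniform(1.5, 2.0, size=30)
        ours = atom_sasa(centers, radii, n_dots=2000)
        arr = struc.AtomArray(30)
        arr.coord = centers.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.res_id = np.arange(1, 31)
        arr.atom_name = np.array(["CA"] * 30)
        arr.res_name = np.array(["ALA"] * 30)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                            vdw_radii=radii)
        assert np.allclose(ours, theirs, rtol=0.05, atol=1.0)

    def test_full_atom_mode_used_when_atoms_present(self):
        cfg = SyntheticConfig(n_residues=30, unresolved_fraction=0.0,
                              backbone=True, seed=25)
        model, _, _ = make_structure(cfg)
        rsa = compute_rsa(model)
        assert np.all(rsa[~np.isnan(rsa)] >= 0)
        assert np.all(rsa[~np.isnan(rsa)] <= 1.5)

    def test_ca_sphere_radius_consistent_with_table(self):
        for aa, area in MAX_ASA.items():
            r = ca_sphere_radius(aa) + 1.4
            assert 4 * np.pi * r * r == pytest.approx(area, rel=1e-6) or \
                ca_sphere_radius(aa) == 1.0


class TestRsaSummary:
    def test_uniform_rsa_both_classes_equal(self):
        rsa = np.full(10, 0.3)
        out = rsa_summary(rsa, "EEEEECCCCC")
        assert out["strand"]["mean_rsa_percent"] == pytest.approx(30.0)
        assert out["other"]["mean_rsa_percent"] == pytest.approx(30.0)

    def test_subset_restriction_hand_computed(self):
        rsa = np.array([0.1, 0.2, 0.9, 0.4])
        out = rsa_summary(rsa, "EECC", sequence="KAKY", residue_subset={"K", "Y"})
        assert out["strand"]["mean_rsa_percent"] == pytest.approx(10.0)  # K1 only
        assert out["other"]["mean_rsa_percent"] == pytest.approx(65.0)  # K3, Y4
        assert (out["strand"]["n"], out["other"]["n"]) == (1, 2)

    def test_weighted_class_means_reconstruct_overall(self):
        rng = np.random.default_rng(2)
        rsa = rng.uniform(0, 1, 40)
        ss = "".join(rng.choice(list("EHC"), 40))
        out = rsa_summary(rsa, ss)
        n_e, n_o = out["strand"]["n"], out["other"]["n"]
        weighted = (out["strand"]["mean_rsa_percent"] * n_e +
                    out["other"]["mean_rsa_percent"] * n_o) / (n_e + n_o)
        assert weighted == pytest.approx(100 * rsa.mean())

    def test_empty_class_reported_absent(self):
        out = rsa_summary(np.array([0.5, 0.5]), "CC")
        assert out["strand"]["mean_rsa_percent"] is None
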