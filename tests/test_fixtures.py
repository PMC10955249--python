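import hashlib
import os

import numpy as np

from autogvp import fixtures


def _sha(path):
    return hashlib.sha256(open(path, "rb").read()).hexdigest()


class TestCatalog:
    def test_branch_coverage(self, catalog):
        assert len(catalog) >= 60
        labels = [sc.label for sc in catalog]
        assert len(set(labels)) == len(labels)
        states = {sc.clinvar_state for sc in catalog}
        assert states >= {
            "absent", "stars0", "stars1_single", "stars1_conflict",
            "stars2plus", "non_standard",
        }

    def test_expectations_filled(self, catalog):
        for sc in catalog:
            assert sc.expected_call_most_severe is not None
            assert sc.expected_call_no_concept is not None
            assert sc.expected_source in ("ClinVar", "InterVar")


class TestGenerateBundle:
    def test_deterministic_bytes(self, bundle, catalog, tmp_path):
        again = fixtures.generate_bundle(catalog, seed=7, out_dir=str(tmp_path / "b2"))
        for name, path in bundle.items():
            assert _sha(path) == _sha(again[name]), name

    def test_different_seed_different_positions(self, bundle, catalog, tmp_path):
        other = fixtures.generate_bundle(catalog, seed=8, out_dir=str(tmp_path / "b3"))
        assert _sha(bundle["vep_vcf"]) != _sha(other["vep_vcf"])

    def test_empty_scenario_list_header_only(self, tmp_path):
        paths = fixtures.generate_bundle([], seed=1, out_dir=str(tmp_path / "empty"))
        for name in ("multianno", "intervar", "autopvs1", "expected_calls"):
            assert len(open(paths[name]).read().splitlines()) == 1
        vcf_lines = open(paths["vep_vcf"]).read().splitlines()
        assert all(line.startswith("#") for line in vcf_lines)


class TestRandomCriteriaVector:
    @staticmethod
    def _flag_fraction(cv):
        flags = list(cv.ps) + list(cv.pm) + list(cv.pp) + [cv.ba1] + list(cv.bs) + list(cv.bp)
        return sum(flags) / len(flags)

    def test_probability_extremes(self):
        rng = np.random.default_rng(0)
        assert self._flag_fraction(fixtures.random_criteria_vector(rng, p=0.0)) == 0.0
        assert self._flag_fraction(fixtures.random_criteria_vector(rng, p=1.0)) == 1.0

    def test_mean_flag_fraction_concentrates(self):
        rng = np.random.default_rng(42)
        fractions = [
            self._flag_fraction(fixtures.random_criteria_vector(rng, p=0.2))
            for _ in range(1000)
        ]
        assert abs(float(np.mean(fractions)) - 0.2) < 0.04

    def test_pvs1_covers_all_strengths(self):
        rng = np.random.default_rng(1)
        seen = {fixtures.random_criteria_vector(rng).pvs1 for _ in range(200)}
        assert len(seen) == 5
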