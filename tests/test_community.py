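import numpy as np
import pandas as pd
import pytest

from taxenv.community import (
    CommunityMatrix,
    EnvironmentLabel,
    HierarchyError,
    LabelledSample,
    build_matrix,
    classified_fraction,
    expected_counts,
    load_hierarchy,
    read_labels,
    size_normalize,
)
from taxenv.taxonomy import RankedTaxon


def fam(name):
    return RankedTaxon.from_names(["P1", "C1", "O1", name])


class TestHierarchy:
    def test_bundled_counts(self):
        h = load_hierarchy()
        assert len(h.supertypes) == 5
        assert len(h.types) == 20
        assert len(h.subtypes) == 46

    def test_every_subtype_has_one_parent_type(self):
        h = load_hierarchy()
        for sub, parent in h.subtype_parent.items():
            assert parent in h.type_parent

    def test_malformed_definition_rejected(self):
        with pytest.raises(HierarchyError):
            load_hierarchy("Aquatic: [not, a, mapping]")
        with pytest.raises(HierarchyError, match="duplicate type"):
            load_hierarchy({"A": {"T": []}, "B": {"T": []}})

    def test_label_validation(self):
        h = load_hierarchy()
        EnvironmentLabel("Thermal", "Geothermal").validate(h)
        with pytest.raises(HierarchyError):
            EnvironmentLabel("Thermal", "Soil").validate(h)
        with pytest.raises(HierarchyError):
            EnvironmentLabel("Aquatic", "Freshwaters", "Grassland").validate(h)

    def test_label_category_by_level(self):
        label = EnvironmentLabel("Aquatic", "Freshwaters", "Rivers")
        assert label.category("supertype") == "Aquatic"
        assert label.category("type") == "Freshwaters"
        assert label.category("subtype") == "Freshwaters/Rivers"
        bare = EnvironmentLabel("Thermal", "Geothermal")
        assert bare.category("subtype") == "Geothermal"


class TestBuildMatrix:
    def _samples(self, mapping):
        return [
            LabelledSample(s, [EnvironmentLabel("Aquatic", t) for t in types])
            for s, types in mapping.items()
        ]

    def test_distinct_otus_not_occurrences(self):
        samples = self._samples({"s1": ["Freshwaters"], "s2": ["Freshwaters"], "s3": ["Freshwaters"]})
        m = build_matrix(
            samples, {"o1": fam("F")}, {"o1": {"s1", "s2", "s3"}}, level="type"
        )
        assert m.counts.loc["F", "Freshwaters"] == 1

    def test_singleton_excluded(self):
        samples = self._samples({"s1": ["Freshwaters"]})
        m = build_matrix(samples, {"o1": fam("F")}, {"o1": {"s1"}}, level="type")
        assert m.counts.empty or (m.counts.values == 0).all()
        m2 = build_matrix(
            samples, {"o1": fam("F")}, {"o1": {"s1"}}, level="type",
            exclude_singletons=False,
        )
        assert m2.counts.loc["F", "Freshwaters"] == 1

    def test_multilabel_counts_everywhere(self):
        samples = [
            LabelledSample(
                "s1",
                [
                    EnvironmentLabel("Aquatic", "Freshwaters"),
                    EnvironmentLabel("Aquatic", "Saline waters"),
                ],
            ),
            LabelledSample("s2", [EnvironmentLabel("Aquatic", "Freshwaters")]),
        ]
        m = build_matrix(samples, {"o1": fam("F")}, {"o1": {"s1", "s2"}}, level="type")
        assert m.counts.loc["F", "Freshwaters"] == 1
        assert m.counts.loc["F", "Saline waters"] == 1

    def test_matches_brute_force_tally(self, rng):
        for _ in range(50):
            n_samples, n_otus = 6, 8
            sample_ids = [f"s{i}" for i in range(n_samples)]
            types = ["Freshwaters", "Saline waters", "Soil"]
            supers = {"Freshwaters": "Aquatic", "Saline waters": "Aquatic", "Soil": "Terrestrial"}
            labels = {s: types[rng.integers(0, 3)] for s in sample_ids}
            samples = [
                LabelledSample(s, [EnvironmentLabel(supers[t], t)])
                for s, t in labels.items()
            ]
            families = [f"F{k}" for k in range(3)]
            otu_taxa = {f"o{k}": fam(families[rng.integers(0, 3)]) for k in range(n_otus)}
            presence = {
                f"o{k}": {s for s in sample_ids if rng.random() < 0.4}
                for k in range(n_otus)
            }
            presence = {k: v for k, v in presence.items() if v}
            m = build_matrix(samples, otu_taxa, presence, level="type")
            for taxon in m.taxa:
                for env in m.environments:
                    expected = sum(
                        1
                        for otu, pres in presence.items()
                        if len(pres) > 1
                        and otu_taxa[otu].name == taxon
                        and any(labels[s] == env for s in pres)
                    )
                    assert m.counts.loc[taxon, env] == expected

    def test_aggregation_not_additive_across_levels(self):
        # one OTU present in samples of two types of one supertype must be
        # counted once at supertype level, not twice
        samples = [
            LabelledSample("s1", [EnvironmentLabel("Aquatic", "Freshwaters")]),
            LabelledSample("s2", [EnvironmentLabel("Aquatic", "Saline waters")]),
        ]
        presence = {"o1": {"s1", "s2"}}
        at_type = build_matrix(samples, {"o1": fam("F")}, presence, level="type")
        at_super = build_matrix(samples, {"o1": fam("F")}, presence, level="supertype")
        assert at_type.counts.loc["F"].sum() == 2
        assert at_super.counts.loc["F", "Aquatic"] == 1


class TestExpectedCounts:
    def test_symmetric_diagonal(self):
        m = pd.DataFrame([[10, 0], [0, 10]])
        assert np.allclose(expected_counts(m), 5.0)

    def test_already_independent(self):
        m = pd.DataFrame([[1, 1], [1, 1]])
        assert np.allclose(expected_counts(m), 1.0)

    def test_matches_chi2_oracle(self, rng):
        from scipy.stats import chi2_contingency

        x = pd.DataFrame(rng.integers(1, 40, (6, 4)))
        e = expected_counts(x)
        oracle = chi2_contingency(x.values)[3]
        assert np.allclose(e.values, oracle)

    def test_preserves_margins(self, small_matrix):
        e = expected_counts(small_matrix)
        assert np.allclose(e.sum(axis=1), small_matrix.counts.sum(axis=1))
        assert np.allclose(e.sum(axis=0), small_matrix.counts.sum(axis=0))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(pd.DataFrame([[0, 0], [0, 0]]))


class TestSizeNormalize:
    def test_divides_by_samples(self):
        counts = pd.DataFrame({"A": [10], "B": [9]}, index=["F"])
        m = CommunityMatrix(counts, pd.Series({"A": 5, "B": 3}))
        out = size_normalize(m)
        assert out.loc["F", "A"] == 2.0
        assert out.loc["F", "B"] == 3.0

    def test_unit_samples_identity(self, small_matrix):
        m = CommunityMatrix(
            small_matrix.counts, pd.Series(1, index=small_matrix.counts.columns)
        )
        assert np.allclose(size_normalize(m), m.counts)

    def test_zero_sample_env_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["F"])
        m = CommunityMatrix.__new__(CommunityMatrix)
        m.counts = counts
        m.n_samples_per_env = pd.Series({"A": 0})
        with pytest.raises(ValueError):
            size_normalize(m)


def test_read_labels_round_trip(tmp_path):
    path = tmp_path / "labels.tsv"
    path.write_text(
        "sample_id\tsupertype\ttype\tsubtype\n"
        "s1\tAquatic\tFreshwaters\tRivers\n"
        "s1\tAquatic\tSaline waters\t\n"
        "s2\tThermal\tGeothermal\t\n"
    )
    samples = read_labels(path, load_hierarchy())
    by_id = {s.sample_id: s for s in samples}
    assert len(by_id["s1"].labels) == 2
    assert by_id["s2"].labels[0].subtype is None


def test_classified_fraction():
    assert round(classified_fraction(3181, 3502)) == 91
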