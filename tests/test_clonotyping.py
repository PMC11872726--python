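import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from bcrpipe import clonotyping as ct
from conftest import make_records


class TestNormalizedHamming:
    def test_identity(self):
        assert ct.normalized_hamming("CARDYW", "CARDYW") == 0.0

    def test_one_substitution_in_ten(self):
        assert ct.normalized_hamming("CARDYGMDVW", "CARDYGMDVF") == pytest.approx(0.10)

    def test_one_in_six_exceeds_default_threshold(self):
        d = ct.normalized_hamming("CARDYW", "CARDFW")
        assert d == pytest.approx(1 / 6)
        assert d > 0.15

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            ct.normalized_hamming("CARW", "CARDW")


class TestPartition:
    def test_lengths_split_groups(self):
        records = make_records(
            [{"junction_aa": "CARDYGMDVGGGW"}, {"junction_aa": "CARDYGMDVGGGGW"}]
        )
        assert len(ct.partition_candidates(records)) == 2

    def test_cross_subject_same_group(self):
        records = make_records(
            [
                {"junction_aa": "CARDYW", "subject_id": "A", "v_call": "IGHV3-30*01"},
                {"junction_aa": "CTRDYW", "subject_id": "B", "v_call": "IGHV3-30*04"},
            ]
        )
        groups = ct.partition_candidates(records)
        assert len(groups) == 1
        (key,) = groups
        assert key == ("IGHV3-30", "IGHJ4", 6)

    def test_empty_input(self):
        assert ct.partition_candidates(make_records([]).iloc[0:0]) == {}


def _brute_force_components(records, threshold=0.15):
    """Independent oracle: connected components of the <=threshold graph
    within each (V, J, length) candidate group."""
    from bcrpipe.io import strip_allele

    labels = {}
    next_label = 0
    keys = records.apply(
        lambda r: (strip_allele(r["v_call"]), strip_allele(r["j_call"]), len(r["junction_aa"])),
        axis=1,
    )
    for key in sorted(set(keys)):
        idx = records.index[keys == key]
        cdr3s = records.loc[idx, "junction_aa"].tolist()
        mat = np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(
            len(cdr3s), len(cdr3s[0])
        )
        dist = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
        adjacency = csr_matrix(dist <= threshold + 1e-12)
        n, comp = connected_components(adjacency, directed=False)
        for row, c in zip(idx, comp):
            labels[row] = (key, next_label + c)
        next_label += n
    return labels


def _partition_as_sets(records, labels):
    out = {}
    for row, label in labels.items():
        out.setdefault(label, set()).add(records.loc[row, "sequence_id"])
    return {frozenset(v) for v in out.values()}


class TestClustering:
    def test_identical_cdr3s_form_one_clonotype(self):
        records = make_records([{"junction_aa": "CARDYW"} for _ in range(3)])
        assignment = ct.cluster_clonotypes(records)
        assert assignment.nunique() == 1

    def test_single_linkage_chains(self):
        # d(A,B)=d(B,C)=1/12 <= 0.15 but d(A,C)=2/12 > 0.15: one clonotype
        a, b, c = "CAAAAAAAAAAW", "CRAAAAAAAAAW", "CRDAAAAAAAAW"
        records = make_records([{"junction_aa": s} for s in (a, b, c)])
        assert ct.cluster_clonotypes(records).nunique() == 1

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            records = _random_instance(rng, n_groups=4, max_seqs=60)
            assignment = ct.cluster_clonotypes(records)
            oracle = _brute_force_components(records)
            assert _partition_as_sets(records, assignment.to_dict()) == _partition_as_sets(
                records, oracle
            )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        records = _random_instance(rng, n_groups=3, max_seqs=50)
        coarse = ct.cluster_clonotypes(records, threshold=0.30)
        fine = ct.cluster_clonotypes(records, threshold=0.10)
        # raising the threshold only merges: every fine cluster is inside one coarse cluster
        mapping = pd.DataFrame({"fine": fine, "coarse": coarse})
        assert (mapping.groupby("fine")["coarse"].nunique() == 1).all()

    def test_record_order_invariance(self):
        rng = np.random.default_rng(9)
        records = _random_instance(rng, n_groups=3, max_seqs=40)
        shuffled = records.sample(frac=1.0, random_state=3).reset_index(drop=True)
        p1 = _partition_as_sets(records, ct.cluster_clonotypes(records).to_dict())
        p2 = _partition_as_sets(shuffled, ct.cluster_clonotypes(shuffled).to_dict())
        assert p1 == p2

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            ct.cluster_clonotypes(make_records([{}]), threshold=0.0)


def _random_instance(rng, n_groups=4, max_seqs=60):
    rows = []
    serial = 0
    for g in range(n_groups):
        length = int(rng.integers(8, 15))
        seeds = ["C" + "".join(rng.choice(list("ADGRSTVY"), length - 2)) + "W" for _ in range(3)]
        for _ in range(int(rng.integers(5, max_seqs))):
            seq = list(seeds[rng.integers(0, 3)])
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(1, length - 1))
                seq[pos] = str(rng.choice(list("ADGRSTVY")))
            rows.append(
                {
                    "sequence_id": f"r{serial:05d}",
                    "junction_aa": "".join(seq),
                    "v_call": f"IGHV{g + 1}-1*01",
                    "subject_id": f"S{serial % 5}",
                }
            )
            serial += 1
    return make_records(rows)


class TestHighUsageSelection:
    def _usage(self, values):
        return pd.DataFrame({"IGHV3-30": values})

    def test_zero_variance_reference(self):
        usage = pd.DataFrame(
            {"IGHV3-30": [0.02, 0.02, 0.02, 0.03]}, index=["h1", "h2", "h3", "c1"]
        )
        groups = pd.Series({"h1": "HC", "h2": "HC", "h3": "HC", "c1": "ME_mm"})
        chosen = ct.select_high_usage_subjects(usage, groups, "IGHV3-30", "ME_mm", "HC")
        assert chosen == ["c1"]

    def test_strict_threshold_arithmetic(self):
        # reference mean 0.02, sd 0.005 -> cutoff 0.025 (strict >)
        usage = pd.DataFrame(
            {"IGHV3-30": [0.015, 0.020, 0.025, 0.030, 0.025]},
            index=["h1", "h2", "h3", "c_hi", "c_edge"],
        )
        groups = pd.Series(
            {"h1": "HC", "h2": "HC", "h3": "HC", "c_hi": "ME_mm", "c_edge": "ME_mm"}
        )
        chosen = ct.select_high_usage_subjects(usage, groups, "IGHV3-30", "ME_mm", "HC")
        assert chosen == ["c_hi"]

    def test_missing_gene(self):
        usage = self._usage([0.1, 0.2])
        usage.index = ["a", "b"]
        with pytest.raises(ValueError):
            ct.select_high_usage_subjects(
                usage, pd.Series({"a": "HC", "b": "ME_mm"}), "IGHV9-99", "ME_mm", "HC"
            )


class TestSubsampleMatched:
    def _records(self, per_subject, subjects):
        rows = []
        for s in subjects:
            for i in range(per_subject):
                rows.append(
                    {"subject_id": s, "junction_aa": f"CAR{i:03d}W", "duplicate_count": 10}
                )
        return make_records(rows)

    def test_exact_depth_retained_entirely(self):
        records = self._records(per_subject=50, subjects=["a1", "a2"])  # 1,000 UMIs
        groups = pd.Series({"a1": "case", "a2": "case"})
        out = ct.subsample_matched(records, groups, n_subjects=2, total_umis=1000)
        assert int(out["duplicate_count"].sum()) == 1000

    def test_umi_conservation_and_determinism(self):
        records = self._records(per_subject=100, subjects=["a1", "a2", "b1", "b2"])
        groups = pd.Series({"a1": "case", "a2": "case", "b1": "ctrl", "b2": "ctrl"})
        out1 = ct.subsample_matched(
            records, groups, n_subjects=2, total_umis=500, rng=np.random.default_rng(5)
        )
        out2 = ct.subsample_matched(
            records, groups, n_subjects=2, total_umis=500, rng=np.random.default_rng(5)
        )
        for prefix in ("a", "b"):
            side = out1[out1["subject_id"].str.startswith(prefix)]
            assert int(side["duplicate_count"].sum()) == 500
        pd.testing.assert_frame_equal(out1, out2)

    def test_insufficient_umis_raise(self):
        records = self._records(per_subject=10, subjects=["a1", "a2"])
        groups = pd.Series({"a1": "case", "a2": "case"})
        with pytest.raises(ValueError, match="UMIs"):
            ct.subsample_matched(records, groups, n_subjects=2, total_umis=10_000)


class TestNetwork:
    def test_clique_for_small_clonotype(self):
        records = make_records([{"junction_aa": "CARDYW"} for _ in range(3)])
        assignment = ct.cluster_clonotypes(records)
        network = ct.build_network(records, assignment, edge_cap=50)
        assert network.graph.number_of_edges() == 3
        assert not network.capped_clonotypes

    def test_singletons_have_no_edges(self):
        rows = [{"junction_aa": f"C{'AD'[i % 2]}{i:03d}DYW"} for i in range(100)]
        records = make_records(rows)
        assignment = pd.Series(
            [f"CT{i:06d}" for i in range(100)], index=records.index, name="clonotype_id"
        )
        network = ct.build_network(records, assignment)
        assert network.graph.number_of_nodes() == 100
        assert network.graph.number_of_edges() == 0

    def test_star_fallback_above_cap(self):
        records = make_records([{"junction_aa": "CARDYW"} for _ in range(200)])
        assignment = ct.cluster_clonotypes(records)
        network = ct.build_network(records, assignment, edge_cap=50)
        assert network.graph.number_of_edges() == 199
        assert len(network.capped_clonotypes) == 1
        degrees = dict(network.graph.degree())
        assert max(degrees.values()) == 199  # hub

    def test_graphml_export(self, tmp_path):
        records = make_records([{"junction_aa": "CARDYW"} for _ in range(3)])
        assignment = ct.cluster_clonotypes(records)
        network = ct.build_network(records, assignment)
        path = tmp_path / "net.graphml"
        network.write_graphml(path)
        assert path.stat().st_size > 0
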