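import numpy as np
import pytest

from foldcover import structio
from foldcover.structio import (
    BackboneStructure,
    ContentError,
    Method,
    StructureMetadata,
    filter_reference_set,
    match_length_distribution,
    read_backbone,
    read_manifest,
    write_backbone,
)
from foldcover.synth import TorsionSpec, build_backbone

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.997   2.831   0.100  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.705   0.200  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.600   0.300  1.00  0.00           O
ATOM      9  N   GLY A   3       6.200   3.830   0.200  1.00  0.00           N
ATOM     10  CA  GLY A   3       7.650   3.860   0.300  1.00  0.00           C
ATOM     11  C   GLY A   3       8.250   5.260   0.300  1.00  0.00           C
ATOM     12  O   GLY A   3       7.550   6.270   0.400  1.00  0.00           O
END
"""

CA_ONLY_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


class TestReadBackbone:
    def test_minimal_three_residue_parse(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        bb, meta = read_backbone(p)
        assert bb.length == 3
        assert meta.resolution is None and meta.method is None
        np.testing.assert_allclose(bb.coords[0, 1], [1.458, 0.0, 0.0])

    def test_ca_only_names_missing_atoms(self, tmp_path):
        p = tmp_path / "ca.pdb"
        p.write_text(CA_ONLY_PDB)
        with pytest.raises(ContentError, match="missing"):
            read_backbone(p)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(structio.FormatError):
            read_backbone(tmp_path / "nope.pdb")

    def test_spatial_gap_detected_as_chain_break(self, tmp_path):
        s = build_backbone(TorsionSpec.helix(12), id="gap")
        coords = s.coords.copy()
        coords[6:] += np.array([50.0, 0.0, 0.0])  # 8+ A CA-CA jump after idx 5
        gapped = BackboneStructure(id="gap", coords=coords)
        p = tmp_path / "gap.pdb"
        write_backbone(gapped, p)
        bb, _ = read_backbone(p)
        assert 5 in bb.chain_breaks

    def test_numbering_gap_detected_as_chain_break(self, tmp_path):
        p = tmp_path / "renum.pdb"
        lines = MINIMAL_PDB.splitlines()
        # renumber residue 3 -> 10
        lines = [ln.replace("GLY A   3", "GLY A  10") for ln in lines]
        p.write_text("\n".join(lines) + "\n")
        bb, _ = read_backbone(p)
        assert bb.chain_breaks == [1]

    def test_roundtrip_preserves_coordinates_to_pdb_precision(self, tmp_path, mixed40):
        p = tmp_path / "rt.pdb"
        write_backbone(mixed40, p)
        bb, _ = read_backbone(p)
        assert np.abs(bb.coords - mixed40.coords).max() < 1e-3

    def test_header_metadata_roundtrip(self, tmp_path, helix20):
        p = tmp_path / "meta.pdb"
        write_backbone(
            helix20,
            p,
            metadata=StructureMetadata(resolution=2.3, r_free=0.21, method=Method.XRAY),
        )
        _, meta = read_backbone(p)
        assert meta.resolution == pytest.approx(2.3)
        assert meta.r_free == pytest.approx(0.21)
        assert meta.method == Method.XRAY


class TestBackboneStructure:
    def test_rejects_nonfinite_and_short(self):
        with pytest.raises(ValueError):
            BackboneStructure("x", np.full((2, 4, 3), np.nan))
        with pytest.raises(ValueError):
            BackboneStructure("x", np.zeros((1, 4, 3)))

    def test_ca_violation_flagging(self, helix20):
        assert helix20.ca_violations() == []
        squeezed = helix20.coords.copy()
        squeezed[5] = squeezed[4]  # zero CA-CA distance at 4->5
        s = BackboneStructure("bad", squeezed)
        assert 4 in s.ca_violations()


def _rec(res, rfree, method):
    s = build_backbone(TorsionSpec.helix(5), id=f"r{res}")
    return s, StructureMetadata(resolution=res, r_free=rfree, method=method)


class TestFilterReferenceSet:
    def test_threshold_application(self):
        records = [
            _rec(2.5, 0.20, Method.XRAY),
            _rec(3.5, 0.20, Method.XRAY),
            _rec(2.0, 0.30, Method.XRAY),
            _rec(2.0, 0.20, Method.NMR),
        ]
        kept, reasons = filter_reference_set(records)
        assert kept == [records[0]]
        assert reasons["resolution"] == 1
        assert reasons["r_free"] == 1
        assert reasons["nmr"] == 1

    def test_boundary_is_strict(self):
        kept, reasons = filter_reference_set([_rec(3.0, 0.20, Method.XRAY)])
        assert kept == [] and reasons["resolution"] == 1
        kept, reasons = filter_reference_set([_rec(2.0, 0.25, Method.XRAY)])
        assert kept == [] and reasons["r_free"] == 1

    def test_empty_input(self):
        kept, reasons = filter_reference_set([])
        assert kept == [] and sum(reasons.values()) == 0

    def test_missing_metadata_rejected_with_reason(self):
        kept, reasons = filter_reference_set([_rec(None, None, None)])
        assert kept == [] and reasons["missing field"] == 1

    def test_output_is_ordered_subset(self):
        rng = np.random.default_rng(0)
        records = [
            _rec(
                float(rng.uniform(1, 4)),
                float(rng.uniform(0.1, 0.4)),
                Method.NMR if rng.random() < 0.3 else Method.XRAY,
            )
            for _ in range(50)
        ]
        kept, _ = filter_reference_set(records)
        positions = [records.index(r) for r in kept]
        assert positions == sorted(positions)
        assert all(r in records for r in kept)


class TestMatchLengthDistribution:
    def test_exact_multiset_match(self):
        idx, shortfall = match_length_distribution([100, 100, 200, 300], [100, 200], seed=0)
        lengths = sorted([100, 100, 200, 300][i] for i in idx)
        assert lengths == [100, 200]
        assert shortfall == {}
        assert len(set(idx)) == len(idx)

    def test_no_candidate_is_shortfall(self):
        idx, shortfall = match_length_distribution([100], [150], seed=0)
        assert idx == [] and shortfall == {150: 1}

    def test_seed_changes_choice_but_not_length(self):
        chosen = set()
        for seed in range(10):
            idx, _ = match_length_distribution([100, 100], [100], seed=seed)
            assert len(idx) == 1 and idx[0] in (0, 1)
            chosen.add(idx[0])
        assert chosen == {0, 1}  # both candidates reachable across seeds

    def test_determinism(self):
        a = match_length_distribution(list(range(50)) * 2, list(range(50)), seed=7)
        b = match_length_distribution(list(range(50)) * 2, list(range(50)), seed=7)
        assert a == b

    def test_multiset_property_random(self):
        rng = np.random.default_rng(3)
        samples = rng.integers(50, 60, size=200).tolist()
        reference = rng.integers(50, 60, size=80).tolist()
        idx, shortfall = match_length_distribution(samples, reference, seed=1)
        selected = sorted(samples[i] for i in idx)
        satisfiable = []
        from collections import Counter

        avail = Counter(samples)
        for ln in reference:
            if avail[ln] > 0:
                avail[ln] -= 1
                satisfiable.append(ln)
        assert selected == sorted(satisfiable) or not shortfall

    def test_exhausted_bin_falls_back_with_replacement(self):
        with pytest.warns(UserWarning, match="replacement"):
            idx, shortfall = match_length_distribution([100], [100, 100, 100], seed=0)
        assert idx == [0, 0, 0] and shortfall == {}


class TestManifest:
    def test_manifest_overrides_header(self, tmp_path, helix20):
        pdb = tmp_path / "s.pdb"
        write_backbone(helix20, pdb, metadata=StructureMetadata(resolution=1.0))
        man = tmp_path / "manifest.tsv"
        man.write_text(
            "id\tpath\tresolution\tr_free\tmethod\nmyid\ts.pdb\t2.8\t0.19\tXRAY\n"
        )
        records = read_manifest(man)
        assert len(records) == 1
        bb, meta = records[0]
        assert bb.id == "myid"
        assert meta.resolution == pytest.approx(2.8)
        assert meta.r_free == pytest.approx(0.19)
        assert meta.method == Method.XRAY
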