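import itertools

import pytest

from ncorfkit import (
    DEFAULT_THRESHOLDS,
    CatalogReport,
    ValidationError,
    assign_host_transcript,
    assign_names,
    build_catalog,
    classify_orf_type,
    cluster_isoforms,
    collapse_identical,
    map_and_exclude,
    orf_codons,
    read_catalog,
    read_orfs,
    write_catalog,
)
from ncorfkit.catalog import (
    ClassificationError,
    length_bin_label,
    length_pass_comparison,
    pct,
    retained_after_removals,
)
from ncorfkit.simulate import SimulationConfig, simulate_annotation, simulate_psites

from conftest import make_orf, make_transcript


class TestStageAccounting:
    def test_conservation_from_counts(self):
        r = CatalogReport.from_stage_counts(
            compiled=100, duplicate=20, unmapped=5, excluded=10)
        assert r.unique_sequences == 75
        assert r.comprehensive == 65
        r.validate()

    def test_violation_raises(self):
        r = CatalogReport(compiled=10, duplicate=1, unmapped=1,
                          excluded_same_frame=1, excluded_pseudogene=0,
                          comprehensive=5)
        with pytest.raises(ValidationError):
            r.validate()

    def test_primary_cannot_exceed_comprehensive(self):
        r = CatalogReport.from_stage_counts(10, 0, 0, 0, primary=5)
        r.primary = 11
        with pytest.raises(ValidationError):
            r.validate()

    def test_retained_after_removals(self):
        assert retained_after_removals(100, {"a": 30, "b": 20}) == 50

    def test_pct_and_bins(self):
        assert pct(1, 3, 1) == 33.3
        assert length_bin_label(6) == "1-20"
        assert length_bin_label(20) == "1-20"
        assert length_bin_label(21) == "21-40"
        assert length_bin_label(500) == "481-500"
        assert length_bin_label(501) == ">500"

    def test_length_pass_comparison(self):
        out = length_pass_comparison(70, 100, 30, 100)
        assert out["pct_short"] == 70.0 and out["pct_long"] == 30.0
        assert out["chi2"] > 0 and out["p_value"] < 0.001
        assert out["log10_p"] < -3


class TestCollapse:
    def test_identical_records_merge_sources(self):
        a = make_orf([(10, 19)], orf_id="a", source_datasets={"s1"})
        b = make_orf([(10, 19)], orf_id="b", source_datasets={"s2"})
        unique, dups = collapse_identical([a, b])
        assert len(unique) == 1 and dups == 1
        assert unique[0].source_datasets == {"s1", "s2"}

    def test_one_nt_difference_kept_apart(self):
        a = make_orf([(10, 19)], orf_id="a")
        b = make_orf([(13, 22)], orf_id="b")
        unique, dups = collapse_identical([a, b])
        assert len(unique) == 2 and dups == 0

    def test_duplicate_count_matches_pairwise_oracle(self):
        blocks = [[(10 * i, 10 * i + 9)] for i in range(7)]
        orfs = [make_orf(b, orf_id=f"o{i}") for i, b in enumerate(blocks)]
        # add 3 duplicates of distinct originals
        for j, i in enumerate((0, 2, 5)):
            orfs.append(make_orf(blocks[i], orf_id=f"dup{j}"))
        unique, dups = collapse_identical(orfs)
        n_dup_oracle = sum(
            1 for i, o in enumerate(orfs)
            if any(o.identity_key() == p.identity_key() for p in orfs[:i])
        )
        assert len(unique) == 7 and dups == 3 == n_dup_oracle


class TestMapAndExclude:
    def test_simulated_decoys_routed_with_reasons(self, sim_default):
        unique, _ = collapse_identical(list(sim_default.orfs))
        res = map_and_exclude(unique, sim_default.transcripts)
        assert res.unmapped == ["orf_intronic_decoy"]
        reasons = dict(res.excluded)
        assert reasons["orf_clone_decoy"] == "same_frame_cds"
        assert reasons["orf_pseudo_decoy"] == "pseudogene_overlap"
        kept_ids = {o.orf_id for o in res.kept}
        assert "orf_uoORF_1" in kept_ids  # CDS overlap in alternative frame

    def test_same_frame_clone_excluded_shifted_kept(self):
        """An ORF phase-identical to a CDS is excluded; shifted by 1 nt it
        is an alternative frame and kept (oracle: explicit phase compare)."""
        t = make_transcript([(0, 300)], cds=[(90, 210)])
        clone = make_orf([(120, 150)], orf_id="clone")   # (120-90)%3 == 0
        shifted = make_orf([(121, 151)], orf_id="shift")  # phase +1
        res = map_and_exclude([clone, shifted], [t])
        assert dict(res.excluded) == {"clone": "same_frame_cds"}
        assert [o.orf_id for o in res.kept] == ["shift"]
        # oracle: genomic phase sets
        cds_phase = {g: (g - 90) % 3 for g in range(90, 210)}
        for orf, expect_excluded in ((clone, True), (shifted, False)):
            hit = any(cds_phase.get(g) == i % 3
                      for i, g in enumerate(orf.positions()))
            assert hit is expect_excluded

    def test_opposite_strand_pseudogene_kept(self):
        host = make_transcript([(0, 300)], tid="h", gene_biotype="lncRNA",
                               transcript_biotype="lncRNA")
        pseudo = make_transcript([(50, 250)], strand="-", tid="p",
                                 gene_biotype="pseudogene",
                                 transcript_biotype="processed_pseudogene")
        orf = make_orf([(100, 130)], orf_id="o")
        res = map_and_exclude([orf], [host, pseudo])
        assert [o.orf_id for o in res.kept] == ["o"]


class TestAssignHost:
    def test_mane_beats_appris(self, sim_default):
        o = next(x for x in sim_default.orfs if x.orf_id == "orf_uORF_1")
        res = map_and_exclude([o], sim_default.transcripts)
        assert assign_host_transcript(o, res.candidates["orf_uORF_1"]) == "T_A1"

    def test_appris_rank_breaks_tie(self, sim_default):
        o = next(x for x in sim_default.orfs if x.orf_id == "orf_uORF_E")
        res = map_and_exclude([o], sim_default.transcripts)
        # T_E1 (APPRIS 1, TSL 2) beats T_E2 (APPRIS 3, TSL 1)
        assert assign_host_transcript(o, res.candidates["orf_uORF_E"]) == "T_E1"

    def test_readthrough_demoted(self, sim_default):
        o = next(x for x in sim_default.orfs if x.orf_id == "orf_PT_rt")
        res = map_and_exclude([o], sim_default.transcripts)
        # T_D1 is readthrough+coding; T_D2 is an ordinary non-coding sibling
        assert assign_host_transcript(o, res.candidates["orf_PT_rt"]) == "T_D2"

    def test_total_order_under_permutation(self, sim_default):
        o = next(x for x in sim_default.orfs if x.orf_id == "orf_uORF_1")
        res = map_and_exclude([o], sim_default.transcripts)
        cands = res.candidates["orf_uORF_1"]
        choices = {
            assign_host_transcript(o, list(perm))
            for perm in itertools.permutations(cands)
        }
        assert len(choices) == 1

    def test_empty_candidates_error(self):
        with pytest.raises(ValidationError):
            assign_host_transcript(make_orf([(0, 9)]), [])


class TestClassify:
    def test_truth_table_types_recovered(self, sim_default):
        """The classifier re-derives every planted ORF's intended type."""
        by_id = {t.transcript_id: t for t in sim_default.transcripts}
        truth = sim_default.truth.set_index("orf_id")
        unique, _ = collapse_identical(list(sim_default.orfs))
        res = map_and_exclude(unique, sim_default.transcripts)
        checked = 0
        for o in res.kept:
            tid = assign_host_transcript(o, res.candidates[o.orf_id])
            expected = truth.loc[o.orf_id]
            assert tid == expected["host"]
            assert classify_orf_type(o, by_id[tid]) == expected["true_type"]
            checked += 1
        assert checked == 13

    def test_each_branch_directly(self):
        t = make_transcript([(0, 300)], cds=[(90, 210)])
        cases = [
            ([(10, 40)], "uORF"),
            ([(80, 110)], "uoORF"),
            ([(121, 151)], "intORF"),
            ([(240, 270)], "dORF"),
            ([(190, 250)], "doORF"),
        ]
        for blocks, expected in cases:
            assert classify_orf_type(make_orf(blocks), t) == expected

    def test_spanning_all_three_regions_errors(self):
        t = make_transcript([(0, 300)], cds=[(90, 210)])
        with pytest.raises(ClassificationError):
            classify_orf_type(make_orf([(60, 240)]), t)

    def test_lncrna_and_pt_branches(self):
        lnc = make_transcript([(0, 100)], gene_biotype="lncRNA",
                              transcript_biotype="lncRNA")
        assert classify_orf_type(make_orf([(10, 40)]), lnc) == "lncRNA-ORF"
        nc = make_transcript([(0, 100)],
                             transcript_biotype="processed_transcript")
        assert classify_orf_type(make_orf([(10, 40)]), nc) == "PT-ORF"


class TestClusterIsoforms:
    def test_shared_stop_different_starts(self):
        a = make_orf([(10, 40)], orf_id="a")
        b = make_orf([(19, 40)], orf_id="b")  # in frame: (19-10)%3 == 0
        (c,) = cluster_isoforms([a, b])
        flags = c.pairwise[frozenset(("a", "b"))]
        assert not flags["shared_start"] and flags["shared_stop"]
        assert flags["overlap_ge_90"]  # all 7 of b's codons shared

    def test_different_frames_never_cluster(self):
        a = make_orf([(10, 40)], orf_id="a")
        b = make_orf([(11, 41)], orf_id="b")  # same span, +1 frame
        clusters = cluster_isoforms([a, b])
        assert len(clusters) == 2

    def test_singleton_cluster(self):
        (c,) = cluster_isoforms([make_orf([(10, 19)], orf_id="solo")])
        assert c.members == ["solo"] and c.pairwise == {}

    def test_matches_brute_force_transitive_closure(self, sim_default):
        orfs = [o for o in sim_default.orfs if o.orf_id != "orf_uORF_dup"]
        clusters = cluster_isoforms(orfs)
        # oracle: union-find over pairwise codon-set intersection
        codons = {
            o.orf_id: {(o.chrom, o.strand, c.genomic_positions)
                       for c in orf_codons(o)}
            for o in orfs
        }
        parent = {oid: oid for oid in codons}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(codons, 2):
            if codons[a] & codons[b]:
                parent[find(a)] = find(b)
        oracle = {}
        for oid in codons:
            oracle.setdefault(find(oid), set()).add(oid)
        assert (sorted(sorted(c.members) for c in clusters)
                == sorted(sorted(m) for m in oracle.values()))


class TestAssignNames:
    def test_numbering_continues_above_legacy(self):
        a = make_orf([(100, 130)], orf_id="a")
        b = make_orf([(200, 230)], orf_id="b")
        legacy_holder = make_orf([(50, 80)], orf_id="c")
        names = assign_names([a, b, legacy_holder],
                             {"c": "c1riboseqorf5"})
        assert names == {"c": "c1riboseqorf5", "a": "c1riboseqorf6",
                         "b": "c1riboseqorf7"}

    def test_fresh_chromosome_starts_at_1(self):
        o = make_orf([(5, 14)], orf_id="x", chrom="chrX")
        assert assign_names([o]) == {"x": "cXriboseqorf1"}

    def test_duplicate_legacy_errors(self):
        a = make_orf([(0, 9)], orf_id="a")
        b = make_orf([(20, 29)], orf_id="b")
        with pytest.raises(ValidationError):
            assign_names([a, b], {"a": "c1riboseqorf1", "b": "c1riboseqorf1"})

    def test_names_injective_and_deterministic(self, sim_default):
        unique, _ = collapse_identical(list(sim_default.orfs))
        res = map_and_exclude(unique, sim_default.transcripts)
        n1 = assign_names(res.kept)
        n2 = assign_names(list(reversed(res.kept)))
        assert n1 == n2
        assert len(set(n1.values())) == len(n1)


@pytest.fixture(scope="module")
def built():
    cfg = SimulationConfig(seed=7)
    sim = simulate_annotation(cfg)
    track = simulate_psites(sim, cfg)
    records, report = build_catalog(
        sim.orfs, sim.transcripts, {"sim": track},
        {"sim": DEFAULT_THRESHOLDS["bodymap_v45"]})
    return sim, records, report


class TestBuildCatalog:
    def test_stage_conservation(self, built):
        _, _, report = built
        report.validate()
        assert report.compiled == 17
        assert report.duplicate == 1 and report.unmapped == 1
        assert report.excluded == 2 and report.comprehensive == 13

    def test_types_partition_comprehensive(self, built):
        _, records, report = built
        assert sum(report.per_type.values()) == report.comprehensive
        assert records["orf_type"].notna().all()

    def test_ppm_universe_includes_cds(self, built):
        _, _, report = built
        assert any(u.startswith("CDS:") for u in report.ppm_universe)

    def test_legacy_name_kept_and_recorded(self, built):
        _, records, _ = built
        row = records.set_index("orf_id").loc["orf_uORF_1"]
        assert row["name"] == "c1riboseqorf3"
        # the norep-style legacy name is not reused as a catalog name
        lnc = records.set_index("orf_id").loc["orf_lnc_1"]
        assert lnc["legacy_names_v35"] == "c1norep7"
        assert lnc["name"] != "c1norep7"

    def test_catalog_write_read_round_trip(self, built, tmp_path):
        sim, records, _ = built
        orfs_by_id = {o.orf_id: o for o in sim.orfs}
        tsv, bed = tmp_path / "cat.tsv", tmp_path / "cat.bed"
        write_catalog(records, orfs_by_id, tsv, bed)
        back = read_catalog(tsv)
        assert len(back) == len(records)
        for col in ("sim_pif", "sim_uniformity", "sim_dropoff"):
            a = records[col].astype(float).round(6)
            b = back[col].astype(float)
            assert ((a - b).abs().fillna(0) < 1e-9).all()
        # zero-coverage decoy renders as the missing token and is not primary
        row = back.set_index("orf_id").loc["orf_zero_decoy"]
        assert row.isna()["sim_pif"] and not row["primary"]
        # companion BED12 re-parses with catalog names
        bed_orfs = read_orfs(bed)
        assert {o.orf_id for o in bed_orfs} == set(records["name"])

    def test_unclassified_record_rejected(self, built, tmp_path):
        sim, records, _ = built
        broken = records.copy()
        broken.loc[0, "orf_type"] = None
        with pytest.raises(ValidationError):
            write_catalog(broken, {o.orf_id: o for o in sim.orfs},
                          tmp_path / "x.tsv", tmp_path / "x.bed")
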