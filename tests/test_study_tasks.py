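"""Study-level tasks: creation, batch extension, visits, tracks, external IDs."""

import pytest
from scipy import stats

from studyid import (
    BlockLayout,
    CheckAlgorithm,
    KeyPairFile,
    PairKind,
    RandomSource,
    StudyConfig,
    StudyTaskError,
    add_ids,
    add_track,
    add_visit,
    capacity,
    create_ids,
    generate_external,
    layer_interval,
    load_study,
)
from studyid.check_digits import verify
from studyid.id_model import BlockKind, Layer, block_widths, parse_id
from studyid.io_config import save_config
from studyid.study_tasks import ConfigValidationError, baseline_filename


def _numbers(rows, config, col):
    widths = block_widths(config)
    return [
        int(parse_id(row[col], config.layout, widths)[BlockKind.NUMBER.value])
        for row in rows
    ]


@pytest.fixture
def demo(tmp_path, small_config):
    files = create_ids(small_config, base_dir=tmp_path)
    return small_config, load_study(tmp_path / small_config.study_name), files


class TestCreateIds:
    def test_numbers_live_in_their_layer_intervals_and_are_distinct(self, tmp_path):
        cfg = StudyConfig("TRI", BlockLayout.parse("N"), 3, (("", 3),), seed=1)
        files = create_ids(cfg, base_dir=tmp_path)
        (pt,) = [f for f in files if f.pair_kind is PairKind.IDP_IDT]
        (st_file,) = [f for f in files if f.pair_kind is PairKind.IDS_IDT]
        p_nums = _numbers(pt.rows, cfg, 0)
        t_nums = _numbers(pt.rows, cfg, 1)
        s_nums = _numbers(st_file.rows, cfg, 0)
        assert all(x in layer_interval(3, Layer.P) for x in p_nums)
        assert all(x in layer_interval(3, Layer.S) for x in s_nums)
        assert all(x in layer_interval(3, Layer.T) for x in t_nums)
        assert len(set(p_nums) | set(s_nums) | set(t_nums)) == 9

    def test_idt_sets_of_both_files_are_equal(self, demo):
        cfg, state, files = demo
        pt = next(f for f in files if f.pair_kind is PairKind.IDP_IDT)
        st_file = next(f for f in files if f.pair_kind is PairKind.IDS_IDT)
        assert {r[1] for r in pt.rows} == {r[1] for r in st_file.rows}

    def test_personal_ids_carry_visit_zero_study_ids_the_configured_visit(self, demo):
        cfg, state, files = demo
        widths = block_widths(cfg)
        pt = next(f for f in files if f.pair_kind is PairKind.IDP_IDT)
        st_file = next(f for f in files if f.pair_kind is PairKind.IDS_IDT)
        for idp, idt in pt.rows:
            assert parse_id(idp, cfg.layout, widths)["V"] == "0"
            assert parse_id(idt, cfg.layout, widths)["V"] == cfg.visit
        for ids, _ in st_file.rows:
            assert parse_id(ids, cfg.layout, widths)["V"] == cfg.visit

    def test_check_digits_verify_on_every_generated_id(self, demo):
        cfg, state, files = demo
        widths = block_widths(cfg)
        for f in files:
            for left, right in f.rows:
                assert verify(left, cfg.check_algorithm, cfg.layout, widths)
                assert verify(right, cfg.check_algorithm, cfg.layout, widths)

    def test_study_file_order_is_shuffled_away_from_creation_order(self, tmp_path):
        cfg = StudyConfig("BIG", BlockLayout.parse("N"), 5, (("", 1000),), seed=3)
        files = create_ids(cfg, base_dir=tmp_path)
        pt = next(f for f in files if f.pair_kind is PairKind.IDP_IDT)
        st_file = next(f for f in files if f.pair_kind is PairKind.IDS_IDT)
        order_by_idt_pt = [r[1] for r in pt.rows]
        order_by_idt_st = [r[1] for r in st_file.rows]
        assert order_by_idt_pt != order_by_idt_st
        # sorting the shuffled file by ID-T must not reproduce creation order
        rank = {idt: i for i, idt in enumerate(order_by_idt_pt)}
        ranks_in_st = [rank[idt] for idt in order_by_idt_st]
        assert ranks_in_st != sorted(ranks_in_st)

    def test_filenames_follow_the_template(self, demo):
        cfg, state, files = demo
        names = {f.filename for f in files}
        assert names == {
            "DEMO_IDP_IDT_T=_N=10_Baseline.txt",
            "DEMO_IDS_IDT_T=_N=10_Baseline.txt",
        }

    def test_barcode_companions_written(self, demo):
        cfg, state, files = demo
        for f in files:
            assert (state.directory / f.barcode_filename).exists()

    def test_invalid_config_creates_nothing(self, tmp_path, small_config):
        import dataclasses

        bad = dataclasses.replace(small_config, visit="i")
        with pytest.raises(ConfigValidationError):
            create_ids(bad, base_dir=tmp_path)
        assert not (tmp_path / bad.study_name).exists()

    def test_directory_collision_rejected(self, tmp_path, small_config):
        create_ids(small_config, base_dir=tmp_path)
        with pytest.raises(StudyTaskError):
            create_ids(small_config, base_dir=tmp_path)

    def test_same_seed_reproduces_identical_files(self, tmp_path, small_config):
        create_ids(small_config, base_dir=tmp_path / "a", audit=False)
        create_ids(small_config, base_dir=tmp_path / "b", audit=False)
        dir_a = tmp_path / "a" / small_config.study_name
        dir_b = tmp_path / "b" / small_config.study_name
        files_a = sorted(p.name for p in dir_a.iterdir())
        assert files_a == sorted(p.name for p in dir_b.iterdir())
        for name in files_a:
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()


class TestLinkage:
    def test_join_on_idt_recovers_exactly_n_couples(self, demo):
        cfg, state, files = demo
        pt = next(f for f in files if f.pair_kind is PairKind.IDP_IDT)
        st_file = next(f for f in files if f.pair_kind is PairKind.IDS_IDT)
        by_idt = dict((idt, idp) for idp, idt in pt.rows)
        couples = [(by_idt[idt], ids) for ids, idt in st_file.rows]
        assert len(couples) == 10
        assert len({p for p, _ in couples}) == 10
        assert len({s for _, s in couples}) == 10


class TestAddIds:
    def test_extension_merges_and_stays_unique(self, demo):
        cfg, state, _ = demo
        new_files = add_ids(cfg, state, 5, rng=RandomSource(77))
        pt = next(f for f in new_files if f.pair_kind is PairKind.IDP_IDT)
        assert len(pt.rows) == 15
        assert pt.filename == "DEMO_IDP_IDT_T=_N=15_Baseline.txt"
        nums = _numbers(pt.rows, cfg, 0)
        assert len(set(nums)) == 15

    def test_prior_files_archived_as_old(self, demo):
        cfg, state, _ = demo
        add_ids(cfg, state, 5, rng=RandomSource(77))
        names = {p.name for p in state.directory.iterdir()}
        assert "DEMO_IDP_IDT_T=_N=10_Baseline.old" in names
        assert "DEMO_IDP_IDT_T=_N=15_Baseline.txt" in names

    def test_reloaded_state_sees_the_union_of_batches(self, demo):
        cfg, state, _ = demo
        add_ids(cfg, state, 5, rng=RandomSource(77))
        reloaded = load_study(state.directory)
        assert len(reloaded.used["P"]) == 15
        assert reloaded.used["P"] == state.used["P"]

    def test_exhaustion_leaves_files_untouched(self, demo):
        cfg, state, _ = demo
        before = sorted(p.name for p in state.directory.iterdir())
        with pytest.raises(StudyTaskError):
            add_ids(cfg, state, capacity(cfg.k), rng=RandomSource(1))
        assert sorted(p.name for p in state.directory.iterdir()) == before

    def test_pool_can_be_driven_to_exhaustion_then_refuses(self, tmp_path):
        cfg = StudyConfig("FULL", BlockLayout.parse("N"), 2, (("", 10),), seed=2)
        create_ids(cfg, base_dir=tmp_path)
        state = load_study(tmp_path / "FULL")
        add_ids(cfg, state, 15, rng=RandomSource(3))
        add_ids(cfg, state, 5, rng=RandomSource(4))  # pool now full: 30 of 30
        assert len(state.used["P"]) == capacity(2)
        with pytest.raises(StudyTaskError):
            add_ids(cfg, state, 1, rng=RandomSource(5))
        reloaded = load_study(tmp_path / "FULL")
        for layer in ("P", "S", "T"):
            assert len(reloaded.used[layer]) == 30


class TestAddVisit:
    def test_worked_example_replaces_only_the_visit_character(self, tmp_path):
        # baseline pairs (4511, 8021), (6511, 9071), (5781, 7281); new visit A
        cfg = StudyConfig("VIS", BlockLayout.parse("N,V"), 3, (("", 3),), visit="1")
        directory = tmp_path / "VIS"
        directory.mkdir()
        save_config(cfg, directory / "config.xml")
        rows = [("4511", "8021"), ("6511", "9071"), ("5781", "7281")]
        KeyPairFile(
            PairKind.IDS_IDT, "", rows, baseline_filename("VIS", PairKind.IDS_IDT, "", 3)
        ).write(directory)
        state = load_study(directory)
        (out,) = add_visit(cfg, state, "A")
        assert out.rows == [("4511", "451A"), ("6511", "651A"), ("5781", "578A")]
        assert out.filename == "VIS_IDS_IDSA_T=_N=3_V=A.txt"

    def test_check_digit_recomputed_for_new_visit(self, demo):
        cfg, state, _ = demo
        (out,) = add_visit(cfg, state, "2")
        widths = block_widths(cfg)
        for base_id, new_id in out.rows:
            base = parse_id(base_id, cfg.layout, widths)
            new = parse_id(new_id, cfg.layout, widths)
            assert new["N"] == base["N"]
            assert new["V"] == "2" and base["V"] == "1"
            assert verify(new_id, cfg.check_algorithm, cfg.layout, widths)
            # parity changes by 1 when the visit digit changes from 1 to 2
            assert (int(new["X"]) - int(base["X"])) % 10 == 1

    def test_reusing_a_visit_is_rejected(self, demo):
        cfg, state, _ = demo
        add_visit(cfg, state, "2")
        for bad in ("1", "2", "i", "00"):
            with pytest.raises(StudyTaskError):
                add_visit(cfg, state, bad)

    def test_layout_without_visit_block_rejected(self, tmp_path):
        cfg = StudyConfig("NOV", BlockLayout.parse("N"), 3, (("", 3),), seed=1)
        create_ids(cfg, base_dir=tmp_path)
        state = load_study(tmp_path / "NOV")
        with pytest.raises(StudyTaskError):
            add_visit(cfg, state, "2")


class TestAddTrack:
    def test_new_track_starts_with_empty_n0_files(self, tmp_path, tracked_config):
        create_ids(tracked_config, base_dir=tmp_path)
        state = load_study(tmp_path / tracked_config.study_name)
        files = add_track(tracked_config, state, "3")
        assert {f.filename for f in files} == {
            "TRK_IDP_IDT_T=3_N=0_Baseline.txt",
            "TRK_IDS_IDT_T=3_N=0_Baseline.txt",
        }
        assert all(f.rows == [] for f in files)

    def test_duplicate_track_rejected(self, tmp_path, tracked_config):
        create_ids(tracked_config, base_dir=tmp_path)
        state = load_study(tmp_path / tracked_config.study_name)
        with pytest.raises(StudyTaskError):
            add_track(tracked_config, state, "1")

    def test_populated_new_track_is_disjoint_from_existing(self, tmp_path, tracked_config):
        create_ids(tracked_config, base_dir=tmp_path)
        state = load_study(tmp_path / tracked_config.study_name)
        before = {layer: set(state.used[layer]) for layer in ("P", "S", "T")}
        add_track(tracked_config, state, "3")
        add_ids(state.config, state, {"3": 5}, rng=RandomSource(6))
        reloaded = load_study(state.directory)
        for layer in ("P", "S", "T"):
            new = reloaded.used[layer] - before[layer]
            assert len(new) == 5
            assert not (new & before[layer])


class TestGenerateExternal:
    def test_worked_example_shape_project_plus_4_digits(self, tmp_path):
        cfg = StudyConfig("EXTDEMO", BlockLayout.parse("N,V"), 3, (("", 3),), visit="1")
        directory = tmp_path / "EXTDEMO"
        directory.mkdir()
        save_config(cfg, directory / "config.xml")
        rows = [("4511", "8021"), ("6511", "9071"), ("5781", "7281")]
        KeyPairFile(
            PairKind.IDS_IDT, "", rows,
            baseline_filename("EXTDEMO", PairKind.IDS_IDT, "", 3),
        ).write(directory)
        state = load_study(directory)
        (out,) = generate_external(state, "EXT", rng=RandomSource(1))
        assert [ids for ids, _ in out.rows] == ["4511", "5781", "6511"]
        randoms = [ide.removeprefix("EXT") for _, ide in out.rows]
        assert all(len(r) == 4 and r.isdigit() for r in randoms)
        assert len(set(randoms)) == 3
        assert out.filename == "EXTDEMO_IDS_IDE_T=_N=3_Prj=EXT.txt"

    def test_check_digit_attached_when_study_ids_carry_one(self, demo):
        cfg, state, _ = demo
        (out,) = generate_external(state, "EXT", rng=RandomSource(2))
        for _, ide in out.rows:
            assert ide.startswith("EXT")
            body, check = ide[:-1], ide[-1]
            assert check.isdigit()
            assert verify(ide, cfg.check_algorithm)
            assert len(body.removeprefix("EXT")) == cfg.k + 1

    def test_duplicate_project_rejected(self, demo):
        cfg, state, _ = demo
        generate_external(state, "EXT", rng=RandomSource(2))
        with pytest.raises(StudyTaskError):
            generate_external(state, "EXT", rng=RandomSource(3))

    def test_two_projects_are_statistically_unlinkable(self, tmp_path):
        cfg = StudyConfig("IND", BlockLayout.parse("N"), 5, (("", 500),), seed=8)
        create_ids(cfg, base_dir=tmp_path)
        state = load_study(tmp_path / "IND")
        (a,) = generate_external(state, "EXTA", rng=RandomSource(21))
        (b,) = generate_external(state, "EXTB", rng=RandomSource(22))
        nums_a = [int(ide.removeprefix("EXTA")) for _, ide in a.rows]
        nums_b = [int(ide.removeprefix("EXTB")) for _, ide in b.rows]
        rho, _ = stats.spearmanr(nums_a, nums_b)
        assert abs(rho) < 0.15

    def test_requires_study_files(self, tmp_path):
        cfg = StudyConfig("EMPTY2", BlockLayout.parse("N"), 3, (("", 3),))
        directory = tmp_path / "EMPTY2"
        directory.mkdir()
        save_config(cfg, directory / "config.xml")
        state = load_study(directory)
        with pytest.raises(StudyTaskError):
            generate_external(state, "EXT", rng=RandomSource(1))


class TestLoadStudy:
    def test_round_trip_counts(self, demo):
        cfg, state, _ = demo
        assert len(state.used["P"]) == 10
        assert len(state.used["S"]) == 10
        assert len(state.used["T"]) == 10

    def test_empty_directory_yields_empty_state(self, tmp_path):
        empty = tmp_path / "EMPTY"
        empty.mkdir()
        state = load_study(empty)
        assert state.config is None
        assert state.files == []

    def test_duplicated_row_is_a_consistency_error(self, demo):
        cfg, state, _ = demo
        path = state.directory / "DEMO_IDP_IDT_T=_N=10_Baseline.txt"
        first = path.read_text().splitlines()[0]
        path.write_text(path.read_text() + first + "\n")
        with pytest.raises(StudyTaskError):
            load_study(state.directory)

    def test_missing_directory_is_an_error(self, tmp_path):
        with pytest.raises(StudyTaskError):
            load_study(tmp_path / "NOPE")


class TestGummRedrawIntegration:
    def test_every_emitted_id_has_a_valid_single_digit_check(self, tmp_path):
        cfg = StudyConfig(
            "GUMM", BlockLayout.parse("N,V,X"), 3, (("", 50),),
            visit="1", check_algorithm=CheckAlgorithm.GUMM_1986, seed=13,
        )
        files = create_ids(cfg, base_dir=tmp_path)
        widths = block_widths(cfg)
        for f in files:
            for left, right in f.rows:
                for id_string in (left, right):
                    assert len(id_string) == cfg.k + 2
                    assert verify(id_string, cfg.check_algorithm, cfg.layout, widths)
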