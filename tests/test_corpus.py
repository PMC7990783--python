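"""Corpus data model, builtin transcription, I/O and subsetting."""

import pytest

import metaor
from metaor.corpus import (
    CorpusError,
    StratumPair,
    StudyCorpus,
    StudyRecord,
    SUBSET_VARIABLES,
    load_studies,
    save_studies,
    subset,
)


def _record(**kw):
    base = dict(study_id="s1", year=2010, country="China", sample_type="tissues",
                control_type="NT", method="MSP", case_m=10, case_u=5,
                ctrl_m=2, ctrl_u=8)
    base.update(kw)
    return StudyRecord(**base)


class TestBuiltinCorpus:
    def test_marginal_totals(self, builtin):
        assert len(builtin) == 8
        assert builtin.total_cases == 476
        assert builtin.total_controls == 385

    @pytest.mark.parametrize("variable,level,k,counts", [
        ("country", "China", 7, (308, 125, 43, 338)),
        ("country", "Poland", 1, (20, 23, 0, 4)),
        ("sample_type", "serum", 2, (100, 16, 11, 132)),
        ("sample_type", "tissues", 6, (228, 132, 32, 210)),
        ("control_type", "NT", 4, (122, 46, 2, 73)),
        ("control_type", "NT&BOT", 3, (176, 69, 39, 236)),
        ("control_type", "AT&NT", 1, (30, 33, 2, 33)),
        ("method", "MSP", 4, (194, 85, 41, 236)),
        ("method", "CCP-based FRET", 1, (27, 8, 2, 9)),
        ("method", "restriction-enzyme", 3, (107, 55, 0, 97)),
        ("size_class", "<100", 5, (152, 79, 4, 106)),
        ("size_class", ">=100", 3, (176, 69, 39, 236)),
    ])
    def test_subgroup_count_rows(self, builtin, variable, level, k, counts):
        sub = subset(builtin, variable, level)
        assert len(sub) == k
        observed = (sum(r.case_m for r in sub), sum(r.case_u for r in sub),
                    sum(r.ctrl_m for r in sub), sum(r.ctrl_u for r in sub))
        assert observed == counts

    def test_one_article_contributes_two_studies(self, builtin):
        twins = [r for r in builtin if r.article_id == "zhou2013"]
        assert {r.sample_type for r in twins} == {"serum", "tissues"}
        assert len({r.study_id for r in twins}) == 2

    @pytest.mark.parametrize("variable,n_studies", [
        ("stage", 7), ("histology", 6), ("grade", 5), ("age", 2),
    ])
    def test_strata_coverage(self, builtin, variable, n_studies):
        carriers = [r for r in builtin
                    if any(p.variable == variable for p in r.strata)]
        assert len(carriers) == n_studies

    def test_stage_strata_totals_within_cases(self, builtin):
        for rec in builtin:
            for pair in rec.strata:
                assert pair.a_n + pair.b_n <= rec.n_case


class TestValidation:
    def test_empty_arm_rejected(self):
        with pytest.raises(CorpusError, match="empty arm"):
            _record(ctrl_m=0, ctrl_u=0)

    def test_negative_count_rejected(self):
        with pytest.raises(CorpusError, match="non-negative"):
            _record(case_m=-1)

    def test_unknown_category_lists_allowed_levels(self):
        with pytest.raises(CorpusError, match="China, Poland"):
            _record(country="France")

    def test_duplicate_study_id_rejected(self):
        with pytest.raises(CorpusError, match="duplicate"):
            StudyCorpus((_record(), _record()))

    def test_stratum_exceeding_cases_rejected(self):
        pair = StratumPair("stage", "III/IV", "I/II", 8, 10, 5, 10)
        with pytest.raises(CorpusError, match="exceed"):
            _record(strata=(pair,))

    def test_stratum_methylated_above_total_rejected(self):
        with pytest.raises(CorpusError, match="methylated"):
            StratumPair("stage", "III/IV", "I/II", 11, 10, 5, 10)


class TestIO:
    def test_round_trip_preserves_corpus(self, builtin, tmp_path):
        studies = tmp_path / "studies.csv"
        strata = tmp_path / "strata.csv"
        save_studies(builtin, studies, strata_path=strata)
        loaded = load_studies(studies, strata_path=strata)
        assert loaded.study_ids == builtin.study_ids
        for a, b in zip(loaded, builtin):
            assert a.counts == b.counts
            assert a.strata == b.strata
            assert (a.country, a.sample_type, a.control_type, a.method) == \
                   (b.country, b.sample_type, b.control_type, b.method)
        assert loaded.digest() == builtin.digest()

    def test_load_rejects_empty_arm_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "study_id,year,country,sample_type,control_type,method,"
            "case_m,case_u,ctrl_m,ctrl_u\n"
            "s1,2010,China,tissues,NT,MSP,5,5,0,0\n")
        with pytest.raises(CorpusError, match="empty arm"):
            load_studies(p)

    def test_load_rejects_duplicate_ids(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "study_id,year,country,sample_type,control_type,method,"
            "case_m,case_u,ctrl_m,ctrl_u\n"
            "s1,2010,China,tissues,NT,MSP,5,5,1,9\n"
            "s1,2011,China,serum,NT,MSP,6,4,1,9\n")
        with pytest.raises(CorpusError, match="duplicate"):
            load_studies(p)

    def test_load_rejects_non_integer_counts(self, tmp_path):
        p = tmp_path / "frac.csv"
        p.write_text(
            "study_id,year,country,sample_type,control_type,method,"
            "case_m,case_u,ctrl_m,ctrl_u\n"
            "s1,2010,China,tissues,NT,MSP,5.5,5,1,9\n")
        with pytest.raises(CorpusError, match="not an integer"):
            load_studies(p)


class TestSubset:
    @pytest.mark.parametrize("variable", SUBSET_VARIABLES)
    def test_partition_property(self, builtin, variable):
        levels = {r.covariate(variable) for r in builtin}
        seen = []
        for level in levels:
            seen.extend(subset(builtin, variable, level).study_ids)
        assert sorted(seen) == sorted(builtin.study_ids)

    def test_subset_preserves_order(self, builtin):
        sub = subset(builtin, "sample_type", "tissues")
        order = [builtin.study_ids.index(s) for s in sub.study_ids]
        assert order == sorted(order)

    def test_unknown_variable_and_level_errors(self, builtin):
        with pytest.raises(CorpusError, match="allowed"):
            subset(builtin, "assay", "MSP")
        with pytest.raises(CorpusError, match="observed levels"):
            subset(builtin, "country", "Japan")
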