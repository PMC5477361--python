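"""The filtering cascade: thresholds, exclusion rules and pipeline behaviour."""

from __future__ import annotations

import random

import pytest

from gpitrio.filters import (
    call_consequence_filter,
    consequence_filter,
    hom_count_filter,
    incidence_estimate,
    maf_filter,
    panel_filter,
    polyphen_filter,
    run_filter_pipeline,
)
from gpitrio.inheritance import InheritanceCall, Model, Origin
from gpitrio.model import (
    Consequence,
    GenePanel,
    PipelineConfig,
    PolyPhen,
    TrioDataset,
    VariantSite,
)
from gpitrio.simulate import (
    DECOY_SPECS,
    SHIPPED_FAMILY_SPECS,
    generate_background_trio,
    plant_decoys,
    plant_family,
)

CFG = PipelineConfig()


def site(maf=0.0, hom_count=0, consequence=Consequence.MISSENSE,
         polyphen=PolyPhen.UNAVAILABLE, gene="PIGT", pos=1000):
    return VariantSite("20", pos, "A", "G", gene=gene, consequence=consequence,
                       polyphen=polyphen, maf=maf, hom_count=hom_count)


def mono(s, origin=Origin.PATERNAL, model=Model.INHERITED_MONOALLELIC):
    return InheritanceCall(model, (s,), (origin,))


def bi(*sites, model=Model.COMPHET_BIALLELIC):
    if model == Model.COMPHET_BIALLELIC:
        return InheritanceCall(model, sites, (Origin.PATERNAL, Origin.MATERNAL))
    return InheritanceCall(model, sites, (Origin.AMBIGUOUS,))


class TestMafFilter:
    PIGV_MAF = 17 / 66_740  # ~0.025%, all heterozygous in the reference

    def test_pigv_frequency_passes_both_thresholds(self):
        assert round(100 * self.PIGV_MAF, 3) == 0.025
        s = site(maf=self.PIGV_MAF)
        assert maf_filter(bi(s, site(maf=self.PIGV_MAF, pos=2000)), CFG)[0]
        strict = PipelineConfig(strict_biallelic_maf=True)
        assert maf_filter(bi(s, site(maf=self.PIGV_MAF, pos=2000)), strict)[0]

    @pytest.mark.parametrize(
        "maf,mono_pass,bi_pass",
        [
            (0.0, True, True),
            (0.005, False, True),   # fails 0.1%, passes 1%
            (0.02, False, False),
            (0.0009, True, True),
        ],
    )
    def test_threshold_arithmetic(self, maf, mono_pass, bi_pass):
        assert maf_filter(mono(site(maf=maf)), CFG)[0] is mono_pass
        pair = bi(site(maf=maf), site(maf=0.0, pos=2000))
        assert maf_filter(pair, CFG)[0] is bi_pass

    def test_monotone_in_threshold(self):
        """Lowering a MAF threshold never lets more calls through."""
        rng = random.Random(11)
        calls = [mono(site(maf=rng.uniform(0, 0.02))) for _ in range(200)]
        survivors = {
            thr: sum(
                maf_filter(c, PipelineConfig(maf_threshold_monoallelic=thr))[0]
                for c in calls
            )
            for thr in (0.0001, 0.001, 0.01)
        }
        assert survivors[0.0001] <= survivors[0.001] <= survivors[0.01]


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,passed",
        [
            (Consequence.SPLICE_ACCEPTOR, True),
            (Consequence.STOP_GAINED, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.MISSENSE, True),
            (Consequence.INFRAME_INDEL, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.OTHER_NONCODING, False),
        ],
    )
    def test_protein_altering_set(self, consequence, passed):
        assert consequence_filter(site(consequence=consequence))[0] is passed


class TestPolyphenFilter:
    def test_inherited_benign_missense_fails(self):
        call = mono(site(polyphen=PolyPhen.BENIGN), Origin.MATERNAL)
        assert not polyphen_filter(call, CFG)[0]

    def test_de_novo_benign_missense_passes(self):
        call = mono(site(polyphen=PolyPhen.BENIGN), Origin.DE_NOVO,
                    Model.DE_NOVO)
        assert polyphen_filter(call, CFG)[0]

    def test_rule_restricted_to_missense(self):
        call = mono(site(consequence=Consequence.STOP_GAINED,
                         polyphen=PolyPhen.UNAVAILABLE))
        assert polyphen_filter(call, CFG)[0]

    def test_benign_site_in_comphet_pair_fails(self):
        pair = bi(site(polyphen=PolyPhen.BENIGN),
                  site(pos=2000, polyphen=PolyPhen.PROBABLY_DAMAGING))
        assert not polyphen_filter(pair, CFG)[0]


class TestHomCountFilter:
    @pytest.mark.parametrize(
        "maf,hom_count,passed",
        [
            (0.004, 5, False),     # inside the band, repeatedly homozygous
            (0.004, 0, True),      # never homozygous in the reference
            (0.00005, 3, True),    # below the 0.1-1.0% band
            (0.001, 2, False),     # band edges inclusive
            (0.01, 2, False),
            (0.004, 1, True),      # a single homozygote is not "multiple"
        ],
    )
    def test_band_and_count(self, maf, hom_count, passed):
        pair = bi(site(maf=maf, hom_count=hom_count), site(pos=2000))
        assert hom_count_filter(pair, CFG)[0] is passed

    def test_monoallelic_calls_not_subject(self):
        call = mono(site(maf=0.0009, hom_count=99))
        assert hom_count_filter(call, CFG)[0]


class TestPanelFilter:
    def test_panel_membership(self):
        assert panel_filter(bi(site(gene="PGAP3"), site(gene="PGAP3", pos=2)),
                            CFG.panel)[0]
        assert not panel_filter(mono(site(gene="SYNGAP1")), CFG.panel)[0]

    def test_empty_panel_is_fatal_at_construction(self):
        with pytest.raises(ValueError, match="empty"):
            GenePanel([])


class TestIncidence:
    @pytest.mark.parametrize(
        "n,total,expected", [(6, 4125, 0.15), (0, 1000, 0.0), (1, 16, 6.25)]
    )
    def test_exact_arithmetic(self, n, total, expected):
        assert incidence_estimate(n, total) == expected

    def test_zero_denominator_fatal(self):
        with pytest.raises(ValueError):
            incidence_estimate(1, 0)


def _plants_and_decoys():
    cohort = []
    for spec in SHIPPED_FAMILY_SPECS:
        cohort.extend(plant_family(spec))
    cohort.extend(plant_decoys())
    return cohort


class TestPipeline:
    def test_planted_families_flagged_without_background(self):
        result = run_filter_pipeline(_plants_and_decoys())
        assert len(result.flagged_trios) == 7
        assert len(result.distinct_flagged_variants()) == 11
        assert result.flagged_genes() == {"PGAP3", "PIGN", "PIGT", "PIGO", "PIGL"}

    def test_decoys_eliminated_at_predicted_stage(self):
        result = run_filter_pipeline(_plants_and_decoys())
        by_id = {t.family.proband.sample_id: t for t in result.trios}
        for spec in DECOY_SPECS:
            t = by_id[spec.proband_id]
            assert not t.is_flagged, spec.family_id
            if spec.expected_fate == "hom_count":
                assert t.eliminated["hom_count"] >= 1
            elif spec.expected_fate == "monoallelic_panel":
                assert len(t.monoallelic_panel) == 1
            elif spec.expected_fate == "incidental":
                assert len(t.incidental) == 1

    def test_pipeline_is_permutation_invariant(self):
        cohort = _plants_and_decoys()
        shuffled = []
        rng = random.Random(3)
        for ds in cohort:
            records = list(ds.records)
            rng.shuffle(records)
            shuffled.append(TrioDataset(ds.family, records, ds.truth))
        rng.shuffle(shuffled)
        assert (
            run_filter_pipeline(cohort).summary()
            == run_filter_pipeline(shuffled).summary()
        )

    def test_stage_counts_balance(self, planted_cohort_result):
        for t in planted_cohort_result.trios:
            survivors = (
                len(t.flagged) + len(t.monoallelic_panel) + len(t.incidental)
            )
            assert t.n_input_calls == sum(t.eliminated.values()) + survivors

    def test_affected_parent_trios_carry_more_candidates(self):
        """Dominant transmission from affected parents inflates the
        exome-wide candidate count, as seen in the cohort stratification."""
        cohort = []
        for i in range(6):
            cohort.append(
                generate_background_trio(3000, seed=100 + i, trio_index=i)
            )
        for i in range(6):
            cohort.append(
                generate_background_trio(
                    3000, seed=200 + i, trio_index=10 + i,
                    mother_affected=True, father_affected=True,
                )
            )
        result = run_filter_pipeline(cohort)
        from gpitrio.inheritance import count_candidates_by_parental_status

        table = count_candidates_by_parental_status(
            (t.family, t.n_exome_candidates) for t in result.trios
        )
        assert table[2]["mean"] > table[0]["mean"]

    def test_hom_ref_background_flags_nothing(self):
        ds = generate_background_trio(500, seed=9)
        quiet = TrioDataset(
            ds.family,
            [r for r in ds.records if not r.child.gt.carries_alt],
            ds.truth,
        )
        result = run_filter_pipeline([quiet])
        assert not result.flagged_trios
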