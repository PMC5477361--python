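"""Domain types and file I/O: VCF round trips, decomposition, PED parsing."""

from __future__ import annotations

import textwrap

import pytest

from gpitrio.io import (
    read_config,
    read_panel,
    read_ped,
    read_trio_vcf,
    write_candidate_report,
    write_trio_vcf,
)
from gpitrio.inheritance import InheritanceCall, Model, Origin
from gpitrio.model import (
    Consequence,
    Family,
    GenePanel,
    GenotypeCall,
    Gt,
    Member,
    PipelineConfig,
    Role,
    Sex,
    TrioRecord,
    VariantSite,
)
from gpitrio.simulate import generate_background_trio


def _key(rec):
    return (rec.site.chrom, rec.site.pos, rec.site.ref, rec.site.alt)


class TestVcfRoundTrip:
    def test_write_then_read_reproduces_fields(self, tmp_path):
        ds = generate_background_trio(120, seed=7)
        path = tmp_path / "trio.vcf"
        write_trio_vcf(path, ds.records)
        back = sorted(read_trio_vcf(path, ds.family), key=_key)
        orig = sorted(ds.records, key=_key)
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert _key(a) == _key(b)
            assert a.site.gene == b.site.gene
            assert a.site.consequence == b.site.consequence
            assert a.site.polyphen == b.site.polyphen
            # MAF passes through a float32 INFO field
            assert a.site.maf == pytest.approx(b.site.maf, rel=1e-6)
            assert a.site.hom_count == b.site.hom_count
            for orig_call, back_call in (
                (a.child, b.child), (a.mother, b.mother), (a.father, b.father)
            ):
                assert orig_call.gt == back_call.gt
                assert orig_call.allele_depths == back_call.allele_depths
                assert orig_call.depth == back_call.depth

    def test_empty_vcf_body_yields_empty_stream(self, tmp_path):
        ds = generate_background_trio(5, seed=1)
        path = tmp_path / "empty.vcf"
        write_trio_vcf(path, ds.records)
        lines = [l for l in path.read_text().splitlines() if l.startswith("#")]
        path.write_text("\n".join(lines) + "\n")
        assert list(read_trio_vcf(path, ds.family)) == []

    def test_missing_sample_column_is_fatal(self, tmp_path):
        ds = generate_background_trio(5, seed=1)
        path = tmp_path / "trio.vcf"
        write_trio_vcf(path, ds.records)
        other = Family(
            "F2",
            (
                Member("nope", Sex.FEMALE, Role.PROBAND, True),
                Member(ds.family.mother.sample_id, Sex.FEMALE, Role.MOTHER, False),
                Member(ds.family.father.sample_id, Sex.MALE, Role.FATHER, False),
            ),
        )
        with pytest.raises(ValueError, match="absent"):
            list(read_trio_vcf(path, other))


MULTIALLELIC_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1,length=249250621>
    ##INFO=<ID=GENE,Number=1,Type=String,Description="g">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tkid\tmum\tdad
    1\t1000\t.\tA\tG,T\t.\tPASS\tGENE=PIGT\tGT:AD:DP\t1/2:0,12,14:26\t0/1:15,16,0:31\t0/2:12,0,11:23
    """
)


class TestMultiallelicDecomposition:
    """Hand-decomposed truth for a two-ALT line across three samples.

    For each ALT the other alternate allele is recoded as reference, so
    kid 1/2 becomes het against G and het against T, and per-alt allele
    observations are conserved.
    """

    @pytest.fixture()
    def family(self):
        return Family(
            "F1",
            (
                Member("kid", Sex.FEMALE, Role.PROBAND, True),
                Member("mum", Sex.FEMALE, Role.MOTHER, False),
                Member("dad", Sex.MALE, Role.FATHER, False),
            ),
        )

    def test_two_alts_give_two_records(self, tmp_path, family):
        path = tmp_path / "multi.vcf"
        path.write_text(MULTIALLELIC_VCF)
        records = sorted(read_trio_vcf(path, family), key=lambda r: r.site.alt)
        assert [r.site.alt for r in records] == ["G", "T"]

        against_g, against_t = records
        assert (against_g.child.gt, against_g.mother.gt, against_g.father.gt) == (
            Gt.HET, Gt.HET, Gt.HOM_REF,
        )
        assert (against_t.child.gt, against_t.mother.gt, against_t.father.gt) == (
            Gt.HET, Gt.HOM_REF, Gt.HET,
        )
        assert against_g.child.allele_depths == (0, 12)
        assert against_t.child.allele_depths == (0, 14)
        assert against_t.father.allele_depths == (12, 11)

    def test_decomposition_conserves_allele_observations(self, tmp_path, family):
        path = tmp_path / "multi.vcf"
        path.write_text(MULTIALLELIC_VCF)
        records = list(read_trio_vcf(path, family))
        # the original line carries one G and one T in the kid, one G in
        # mum, one T in dad: per-alt alt-allele counts must match
        alt_counts = {
            rec.site.alt: sum(
                {"hom_ref": 0, "het": 1, "hom_alt": 2}[c.gt.value]
                for c in (rec.child, rec.mother, rec.father)
            )
            for rec in records
        }
        assert alt_counts == {"G": 2, "T": 2}


class TestPed:
    def test_quartet_with_two_affected_brothers(self, tmp_path):
        ped = tmp_path / "fam.ped"
        ped.write_text(
            "FAM1 dad 0 0 1 1\n"
            "FAM1 mum 0 0 2 1\n"
            "FAM1 bro1 dad mum 1 2\n"
            "FAM1 bro2 dad mum 1 2\n"
        )
        (family,) = read_ped(ped)
        assert family.proband.sample_id == "bro1"
        assert [s.sample_id for s in family.siblings] == ["bro2"]
        assert family.siblings[0].affected

    def test_trio_with_unaffected_parents(self, tmp_path):
        ped = tmp_path / "fam.ped"
        ped.write_text(
            "F dad 0 0 1 1\nF mum 0 0 2 1\nF kid dad mum 2 2\n"
        )
        (family,) = read_ped(ped)
        assert family.n_affected_parents == 0
        assert family.proband.sex == Sex.FEMALE

    def test_absent_parent_is_fatal(self, tmp_path):
        ped = tmp_path / "fam.ped"
        ped.write_text("F kid dad mum 1 2\nF mum 0 0 2 1\n")
        with pytest.raises(ValueError, match="absent parent"):
            read_ped(ped)

    def test_cyclic_parent_pointer_is_fatal(self, tmp_path):
        ped = tmp_path / "fam.ped"
        ped.write_text(
            "F a b mum 1 2\nF b a mum 1 1\nF mum 0 0 2 1\n"
        )
        with pytest.raises(ValueError, match="cycl"):
            read_ped(ped)


class TestCandidateReport:
    def _calls(self):
        site_a = VariantSite("17", 37_827_101, "A", "G", gene="PGAP3",
                             consequence=Consequence.MISSENSE, cdna="c.914A>G")
        site_b = VariantSite("17", 37_827_202, "A", "G", gene="PGAP3",
                             consequence=Consequence.MISSENSE, cdna="c.320C>T",
                             maf=1.7e-4)
        return [
            InheritanceCall(
                Model.COMPHET_BIALLELIC, (site_a, site_b),
                (Origin.PATERNAL, Origin.MATERNAL), "FAM-A",
            )
        ]

    def test_report_is_order_invariant_and_deterministic(self, tmp_path):
        calls = self._calls()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_candidate_report(calls, p1)
        write_candidate_report(list(reversed(calls)), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert "c.914A>G" in p1.read_text()

    def test_empty_candidates_give_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_candidate_report([], path)
        assert path.read_text().strip() == (
            "family\tgene\tmodel\tvariant\torigin\tmaf\thom_count"
        )


class TestConfigAndPanel:
    def test_yaml_config_round_trip(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            "maf_threshold_monoallelic: 0.0005\npanel:\n  - PIGT\n  - PIGN\n"
        )
        cfg = read_config(cfg_path)
        assert cfg.maf_threshold_monoallelic == 0.0005
        assert "PIGT" in cfg.panel and "PGAP3" not in cfg.panel

    def test_unknown_key_rejected(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text("not_a_knob: 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            read_config(cfg_path)

    def test_empty_panel_is_fatal(self, tmp_path):
        panel = tmp_path / "panel.txt"
        panel.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            read_panel(panel)

    def test_duplicate_panel_symbol_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenePanel(["PIGT", "PIGT"])


class TestVariantSiteValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pos": 0},
            {"maf": 1.5},
            {"hom_count": -1},
            {"alt": "A"},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(chrom="1", pos=100, ref="A", alt="G")
        base.update(kwargs)
        with pytest.raises(ValueError):
            VariantSite(**base)
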