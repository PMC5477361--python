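"""Rarity, consequence, PolyPhen, homozygote-count and panel filters.

The cascade is applied in a fixed order — classify, pair, MAF,
consequence, PolyPhen, homozygote count, gene panel — so that per-stage
elimination counts are reproducible. In the default recessive-focus
mode only biallelic (and X-hemizygous) calls in panel genes populate
the clinically significant lane; monoallelic panel hits are logged but
not flagged, and off-panel de novo candidates are kept in an incidental
lane.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .inheritance import (
    BIALLELIC_MODELS,
    InheritanceCall,
    Model,
    Origin,
    admit_monoallelic,
    classify_site,
    pair_compound_hets,
    site_origin,
)
from .model import (
    PROTEIN_ALTERING,
    Consequence,
    Family,
    GenePanel,
    Gt,
    PipelineConfig,
    PolyPhen,
    TrioDataset,
    TrioRecord,
    VariantSite,
)

FilterResult = tuple[bool, Optional[str]]

STAGES = ("maf", "consequence", "polyphen", "hom_count", "panel")


def maf_filter(call: InheritanceCall, cfg: PipelineConfig) -> FilterResult:
    """Monoallelic calls must be rarer than the monoallelic threshold;
    biallelic and X-linked calls apply the biallelic threshold to every
    constituent site (or the strict monoallelic one in strict mode)."""
    if call.is_biallelic:
        threshold = (
            cfg.maf_threshold_monoallelic
            if cfg.strict_biallelic_maf
            else cfg.maf_threshold_biallelic
        )
    else:
        threshold = cfg.maf_threshold_monoallelic
    for site in call.variants:
        if site.maf >= threshold:
            return False, f"maf {site.maf:.6g} >= {threshold:g}"
    return True, None


def consequence_filter(site: VariantSite) -> FilterResult:
    if site.consequence in PROTEIN_ALTERING:
        return True, None
    return False, f"consequence {site.consequence.value} not protein altering"


def call_consequence_filter(call: InheritanceCall) -> FilterResult:
    for site in call.variants:
        ok, reason = consequence_filter(site)
        if not ok:
            return False, reason
    return True, None


def polyphen_filter(call: InheritanceCall, cfg: PipelineConfig) -> FilterResult:
    """Exclude inherited missense variants predicted benign; de novo
    benign missense and non-missense classes are untouched, as is a
    missing prediction."""
    if not cfg.polyphen_exclude_inherited_benign:
        return True, None
    for site, origin in zip(call.variants, call.origins):
        if (
            site.consequence == Consequence.MISSENSE
            and site.polyphen == PolyPhen.BENIGN
            and origin != Origin.DE_NOVO
        ):
            return False, f"inherited benign missense {site.variant_id}"
    return True, None


def hom_count_filter(call: InheritanceCall, cfg: PipelineConfig) -> FilterResult:
    """Biallelic calls only: exclude when any constituent site sits in
    the 0.1-1.0% MAF band and has been seen homozygous in the reference
    cohort at least ``hom_count_exclusion_min`` times."""
    if not call.is_biallelic:
        return True, None
    lo, hi = cfg.hom_count_maf_band
    for site in call.variants:
        if lo <= site.maf <= hi and site.hom_count >= cfg.hom_count_exclusion_min:
            return False, (
                f"{site.variant_id}: maf {site.maf:.4g} in hom-exclusion band "
                f"with {site.hom_count} reference homozygotes"
            )
    return True, None


def panel_filter(call: InheritanceCall, panel: GenePanel) -> FilterResult:
    if call.gene in panel:
        return True, None
    return False, f"gene {call.gene} not in panel"


def incidence_estimate(n_diagnosed_families: int, n_independent_families: int) -> float:
    """Percentage of independent families diagnosed, to two decimals."""
    if n_independent_families <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= n_diagnosed_families <= n_independent_families:
        raise ValueError("diagnosed count must be within [0, total]")
    return round(100.0 * n_diagnosed_families / n_independent_families, 2)


# ---------------------------------------------------------------------------
# The full cascade


@dataclass
class TrioFilterResult:
    family: Family
    flagged: list[InheritanceCall] = field(default_factory=list)
    monoallelic_panel: list[InheritanceCall] = field(default_factory=list)
    incidental: list[InheritanceCall] = field(default_factory=list)
    eliminated: Counter = field(default_factory=Counter)
    n_input_calls: int = 0
    n_exome_candidates: int = 0
    n_mendelian_violations: int = 0
    n_qc_dropped: int = 0
    n_monoallelic_not_admitted: int = 0

    @property
    def is_flagged(self) -> bool:
        return bool(self.flagged)


@dataclass
class PipelineResult:
    trios: list[TrioFilterResult]
    config: PipelineConfig

    @property
    def flagged_trios(self) -> list[TrioFilterResult]:
        return [t for t in self.trios if t.is_flagged]

    def distinct_flagged_variants(self) -> set[str]:
        return {
            site.variant_id
            for t in self.flagged_trios
            for call in t.flagged
            for site in call.variants
        }

    def flagged_genes(self) -> set[str]:
        return {call.gene for t in self.flagged_trios for call in t.flagged}

    def stage_counts(self) -> Counter:
        total: Counter = Counter()
        for t in self.trios:
            total.update(t.eliminated)
        return total

    def summary(self) -> dict:
        elim = self.stage_counts()
        return {
            "n_trios": len(self.trios),
            "n_flagged_trios": len(self.flagged_trios),
            "flagged_trios": sorted(
                t.family.proband.sample_id for t in self.flagged_trios
            ),
            "n_distinct_variants": len(self.distinct_flagged_variants()),
            "distinct_variants": sorted(self.distinct_flagged_variants()),
            "n_genes": len(self.flagged_genes()),
            "genes": sorted(self.flagged_genes()),
            "eliminated_by_stage": {s: elim.get(s, 0) for s in STAGES},
            "n_monoallelic_panel_logged": sum(
                len(t.monoallelic_panel) for t in self.trios
            ),
            "n_incidental": sum(len(t.incidental) for t in self.trios),
            "n_mendelian_violations": sum(
                t.n_mendelian_violations for t in self.trios
            ),
        }


def _qc_pass(record: TrioRecord, cfg: PipelineConfig) -> bool:
    if not record.site.qc_pass:
        return False
    child = record.child
    if cfg.min_depth and child.depth < cfg.min_depth:
        return False
    if cfg.min_allele_fraction and child.gt in (Gt.HET, Gt.HOM_ALT, Gt.HEMI_ALT):
        ref_d, alt_d = child.allele_depths
        total = ref_d + alt_d
        if total > 0 and alt_d / total < cfg.min_allele_fraction:
            return False
    return True


def build_calls(dataset: TrioDataset, cfg: PipelineConfig,
                result: TrioFilterResult) -> list[InheritanceCall]:
    """Classification + compound-het pairing for one trio."""
    family = dataset.family
    fam_id = family.family_id
    child_sex = family.proband.sex
    calls: list[InheritanceCall] = []
    het_by_gene: dict[str, list[TrioRecord]] = defaultdict(list)

    for record in dataset.records:
        if not _qc_pass(record, cfg):
            result.n_qc_dropped += 1
            continue
        labels = classify_site(record, child_sex)
        if not labels and record.child.gt.carries_alt:
            # carries the allele but fits no model: transmission violation
            result.n_mendelian_violations += 1
        for model, origin in labels:
            if model == Model.INHERITED_MONOALLELIC and not admit_monoallelic(
                origin, family
            ):
                result.n_monoallelic_not_admitted += 1
                continue
            calls.append(InheritanceCall(model, (record.site,), (origin,), fam_id))
        if record.child.gt == Gt.HET and record.site.gene != ".":
            het_by_gene[record.site.gene].append(record)

    for gene, records in het_by_gene.items():
        if len(records) >= 2:
            calls.extend(
                pair_compound_hets(records, fam_id, cfg.include_ambiguous_comphet)
            )
    return calls


def filter_trio(dataset: TrioDataset, cfg: PipelineConfig) -> TrioFilterResult:
    result = TrioFilterResult(family=dataset.family)
    calls = build_calls(dataset, cfg, result)
    result.n_input_calls = len(calls)

    survivors = []
    for call in calls:
        for stage, check in (
            ("maf", lambda c: maf_filter(c, cfg)),
            ("consequence", call_consequence_filter),
            ("polyphen", lambda c: polyphen_filter(c, cfg)),
            ("hom_count", lambda c: hom_count_filter(c, cfg)),
        ):
            ok, _reason = check(call)
            if not ok:
                result.eliminated[stage] += 1
                break
        else:
            survivors.append(call)

    # survivors are exome-wide candidates irrespective of the panel
    result.n_exome_candidates = len(survivors)

    for call in survivors:
        ok, _ = panel_filter(call, cfg.panel)
        if ok:
            if call.is_biallelic or not cfg.recessive_focus:
                result.flagged.append(call)
            else:
                result.monoallelic_panel.append(call)
        elif call.model == Model.DE_NOVO:
            result.incidental.append(call)
        else:
            result.eliminated["panel"] += 1

    def call_key(c: InheritanceCall):
        return (c.gene, c.model.value, tuple(s.pos for s in c.variants))

    for lane in (result.flagged, result.monoallelic_panel, result.incidental):
        lane.sort(key=call_key)
    return result


def run_filter_pipeline(
    cohort: Iterable[TrioDataset], cfg: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Run the full cascade over a cohort of trios.

    Output ordering is deterministic (sorted by family id, proband id)
    and invariant to the input order of trios and of records within a
    trio.
    """
    cfg = cfg or PipelineConfig()
    results = [filter_trio(ds, cfg) for ds in cohort]
    results.sort(key=lambda t: (t.family.family_id, t.family.proband.sample_id))
    return PipelineResult(results, cfg)
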