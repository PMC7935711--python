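"""End-to-end orchestration: catalog -> match -> prefilter -> clinical filter -> report.

Observations, not variants, are the unit of accounting: a catalog variant
seen in two probands contributes two observations. Counts are conserved at
every stage boundary and asserted in the run manifest, and every excluded
observation carries its full rule trace so false negatives are auditable.
Output ordering is canonicalized (chromosome, position, proband) so repeated
runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .clinical_filter import FilterDecision, Status, apply_standard_filter
from .clinvar_catalog import build_catalog
from .cohort_match import (
    DropReason,
    VariantObservation,
    carrier_family_count,
    internal_maf,
    match_proband,
    prefilter,
)
from .config import Config
from .io_formats import (
    read_annotations,
    read_clinvar_table_counted,
    read_cohort_vcf,
    read_gene_panel,
    read_pedigree,
    write_report,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc


@dataclass
class RunManifest:
    inputs: dict[str, dict] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"inputs": self.inputs, "config": self.config, "counts": self.counts},
            indent=2,
            sort_keys=True,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    decisions: list[FilterDecision]
    dropped: list[tuple[VariantObservation, DropReason]]
    manifest: RunManifest

    def decision_for(self, proband_id: str, key) -> Optional[str]:
        """Outcome label for (proband, variant): status, DROPPED, or None.

        Compound-het decisions cover both members of the pair.
        """
        for decision in self.decisions:
            obs = decision.observation
            if obs.proband.id != proband_id:
                continue
            if obs.key == key or obs.partner_key == key:
                return decision.status.value
        for obs, _reason in self.dropped:
            if obs.proband.id != proband_id:
                continue
            if obs.key == key or obs.partner_key == key:
                return "DROPPED"
        return None


def _fmt(x, digits: int = 6) -> str:
    if x is None:
        return ""
    return f"{x:.{digits}g}"


def _decision_row(
    obs: VariantObservation,
    status: str,
    drop_reason: Optional[DropReason] = None,
    decision: Optional[FilterDecision] = None,
) -> dict:
    ann = obs.annotation
    parent_call = obs.transmitting_call()
    return {
        "family": obs.proband.family_id,
        "proband": obs.proband.id,
        "sex": obs.proband.sex.value,
        "chrom": obs.key.chrom,
        "pos": obs.key.pos,
        "ref": obs.key.ref,
        "alt": obs.key.alt,
        "partner": str(obs.partner_key) if obs.partner_key else "",
        "gene": obs.gene,
        "requirement": obs.requirement.value,
        "genotype_class": obs.genotype_class.value,
        "male_x_het": int(obs.male_x_het),
        "inheritance": obs.inheritance.value,
        "internal_maf": _fmt(obs.internal_maf),
        "stars": "" if obs.stars is None else obs.stars,
        "child_gq": obs.child_call.gq,
        "child_dp": obs.child_call.dp,
        "child_vaf": _fmt(obs.child_call.vaf),
        "parent_vaf": _fmt(parent_call.vaf) if parent_call else "",
        "consequence": ann.consequence if ann else "",
        "missense_predictor": ann.missense_predictor.value if ann else "",
        "population_maf": _fmt(ann.population_maf) if ann else "",
        "population_allele_count": ann.population_allele_count if ann else "",
        "status": status,
        "drop_reason": drop_reason.value if drop_reason else "",
        "primary_reason": (
            decision.primary_reason.value if decision and decision.primary_reason else ""
        ),
        "all_reasons": (
            ",".join(r.value for r in decision.all_reasons) if decision else ""
        ),
        "parental_mosaicism": int(decision.parental_mosaicism) if decision else 0,
    }


def run(
    clinvar_path: str | Path,
    panel_path: str | Path,
    vcf_path: str | Path,
    ped_path: str | Path,
    annotations_path: str | Path,
    config: Config | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full re-screen and optionally write report files.

    Any stage failure aborts with the stage name and the offending record in
    the error message.
    """
    config = config or Config()
    manifest = RunManifest(config=config.to_dict())
    for name, path in [
        ("clinvar", clinvar_path), ("panel", panel_path), ("vcf", vcf_path),
        ("ped", ped_path), ("annotations", annotations_path),
    ]:
        manifest.inputs[name] = {"path": str(path), "sha256": _sha256(path)}

    with _stage("panel"):
        panel = read_gene_panel(panel_path)
    with _stage("catalog"):
        raw_records, n_skipped = read_clinvar_table_counted(clinvar_path)
        catalog = build_catalog(raw_records, panel, config.panel_confidence)
    with _stage("pedigree"):
        pedigree = read_pedigree(ped_path)
    with _stage("genotypes"):
        genotypes = {}
        for key, calls in read_cohort_vcf(vcf_path, pedigree):
            if key in catalog:
                genotypes[key] = calls
    with _stage("internal_maf"):
        mafs = {key: internal_maf(key, calls, pedigree) for key, calls in genotypes.items()}
        indel_family_counts = {
            key: carrier_family_count(calls, pedigree)
            for key, calls in genotypes.items()
            if key.is_indel
        }
    with _stage("annotations"):
        annotations = read_annotations(annotations_path)

    with _stage("match"):
        observations: list[VariantObservation] = []
        for proband in pedigree.probands():
            observations.extend(
                match_proband(proband, pedigree, catalog, genotypes, mafs, config)
            )

    with _stage("prefilter"):
        kept: list[VariantObservation] = []
        dropped: list[tuple[VariantObservation, DropReason]] = []
        for obs in observations:
            reason = prefilter(obs, config, indel_family_counts)
            if reason is None:
                kept.append(obs)
            else:
                dropped.append((obs, reason))

    with _stage("adjudicate"):
        decisions: list[FilterDecision] = []
        for obs in kept:
            obs.annotation = annotations.get(obs.key)
            if obs.annotation is None:
                raise ValueError(f"annotation missing for {obs.key} in {obs.proband.id}")
            if obs.partner is not None:
                obs.partner.annotation = annotations.get(obs.partner.key)
            entry = catalog.panel_index[obs.gene]
            decisions.append(apply_standard_filter(obs, entry, obs.annotation, config))

    def _order(obs: VariantObservation):
        return (obs.key.chrom, obs.key.pos, obs.key.ref, obs.key.alt, obs.proband.id)

    decisions.sort(key=lambda d: _order(d.observation))
    dropped.sort(key=lambda pair: _order(pair[0]))

    n_reported = sum(1 for d in decisions if d.status is Status.REPORTED_STANDARD)
    excluded_by_reason: dict[str, int] = {}
    for d in decisions:
        if d.status is Status.EXCLUDED:
            code = d.primary_reason.value
            excluded_by_reason[code] = excluded_by_reason.get(code, 0) + 1
    dropped_by_reason: dict[str, int] = {}
    for _obs, reason in dropped:
        dropped_by_reason[reason.value] = dropped_by_reason.get(reason.value, 0) + 1

    counts = {
        "catalog_rows": catalog.n_raw,
        "catalog_rows_skipped": n_skipped,
        "catalog_rejected_by_reason": {
            k: v for k, v in sorted(catalog.tally.items()) if k != "eligible"
        },
        "catalog_eligible_raw": catalog.n_eligible_raw,
        "catalog_unique": len(catalog),
        "matched": len(observations),
        "dropped": len(dropped),
        "dropped_by_reason": dropped_by_reason,
        "adjudicated": len(decisions),
        "reported_standard": n_reported,
        "excluded": len(decisions) - n_reported,
        "excluded_by_reason": excluded_by_reason,
    }
    # stage-boundary conservation
    assert counts["matched"] == counts["dropped"] + counts["adjudicated"]
    assert counts["adjudicated"] == counts["reported_standard"] + counts["excluded"]
    assert sum(dropped_by_reason.values()) == counts["dropped"]
    assert sum(excluded_by_reason.values()) == counts["excluded"]
    assert (
        sum(counts["catalog_rejected_by_reason"].values()) + counts["catalog_eligible_raw"]
        == counts["catalog_rows"]
    )
    manifest.counts = counts

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            _decision_row(d.observation, d.status.value, decision=d) for d in decisions
        ] + [
            _decision_row(obs, "DROPPED", drop_reason=reason) for obs, reason in dropped
        ]
        rows.sort(key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"], r["proband"]))
        write_report(rows, out_dir, counts)
        (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")

    return PipelineResult(decisions=decisions, dropped=dropped, manifest=manifest)
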