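"""End-to-end orchestration: variants -> classification -> tree -> dating.

A :class:`RunConfig` names the inputs (FASTA reference and samples, metadata
TSV, haplogroup definitions) and output directory; :func:`run_pipeline`
executes the stages in order, writes every table, and records a manifest
with content digests so that identical configurations yield byte-identical
primary outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .classifier import (
    HaplogroupHierarchy,
    aggregate_frequencies,
    assignments_table,
    classify,
    default_hierarchy,
)
from .dating import clade_stats, stats_table, RATE_YEARS_PER_SUB
from .parsimony_tree import build_tree
from .reference_variants import (
    CODING_REGION,
    CONTROL_REGION,
    HaplotypeProfile,
    ReferenceGenome,
    call_variants,
    profile_table,
)

__all__ = ["RunConfig", "Diagnostic", "RunReport", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    reference_fasta: str
    samples_fasta: str
    metadata_tsv: str
    output_dir: str
    definitions_yaml: Optional[str] = None  # None: the shipped T1 definitions
    rate_years_per_sub: float = RATE_YEARS_PER_SUB
    rounding_decimals: int = 1
    seed: Optional[int] = None
    exact_tree_max: int = 8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class Diagnostic:
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.message}"


@dataclass
class RunReport:
    output_dir: Path
    manifest: Dict
    stage_counts: Dict[str, int] = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, sample_ids: Optional[List[str]] = None):
        self.stage = stage
        self.sample_ids = sample_ids or []
        detail = f" (samples: {', '.join(self.sample_ids)})" if self.sample_ids else ""
        super().__init__(f"stage {stage!r} failed: {message}{detail}")


def _read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def validate_inputs(config: RunConfig) -> List[Diagnostic]:
    """Non-destructive checks: existence, parsability, id consistency."""
    diags: List[Diagnostic] = []
    for label, path in (
        ("reference", config.reference_fasta),
        ("samples", config.samples_fasta),
        ("metadata", config.metadata_tsv),
    ):
        if not Path(path).exists():
            diags.append(Diagnostic("missing-file", f"{label} file not found: {path}"))
    if config.definitions_yaml and not Path(config.definitions_yaml).exists():
        diags.append(
            Diagnostic("missing-file", f"definitions file not found: {config.definitions_yaml}")
        )
    if diags:
        return diags

    refs = _read_fasta(config.reference_fasta)
    if len(refs) != 1:
        diags.append(
            Diagnostic("bad-reference", f"expected one reference record, found {len(refs)}")
        )
    samples: Dict[str, str] = {}
    seen_dupes = set()
    for rec in SeqIO.parse(config.samples_fasta, "fasta"):
        if rec.id in samples and rec.id not in seen_dupes:
            diags.append(Diagnostic("duplicate-sample", f"duplicate sample id {rec.id!r}"))
            seen_dupes.add(rec.id)
        samples[rec.id] = str(rec.seq)
    if not samples:
        diags.append(Diagnostic("empty-fasta", "no sample sequences found"))

    try:
        meta = pd.read_csv(config.metadata_tsv, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - depends on malformed input
        diags.append(Diagnostic("bad-metadata", f"cannot parse metadata: {exc}"))
        return diags
    required = {"sample", "breed", "country", "continent"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        diags.append(
            Diagnostic("bad-metadata", f"metadata lacks columns: {sorted(missing_cols)}")
        )
    else:
        meta_ids = set(meta["sample"])
        for sid in sorted(set(samples) - meta_ids):
            diags.append(Diagnostic("no-metadata", f"sample {sid!r} absent from metadata"))
        for sid in sorted(meta_ids - set(samples)):
            diags.append(Diagnostic("no-sequence", f"metadata row {sid!r} has no sequence"))
        dup = meta["sample"][meta["sample"].duplicated()]
        for sid in sorted(set(dup)):
            diags.append(Diagnostic("duplicate-sample", f"duplicate metadata row {sid!r}"))
    return diags


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Run variants -> classify -> tree -> dating -> frequency tables."""
    fatal = [
        d for d in validate_inputs(config)
        if d.code in ("missing-file", "bad-reference", "empty-fasta", "bad-metadata")
    ]
    if fatal:
        raise PipelineError("validate", "; ".join(map(str, fatal)))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: Dict[str, int] = {}

    refs = _read_fasta(config.reference_fasta)
    (ref_name, ref_seq), = refs.items()
    reference = ReferenceGenome(
        ref_name, ref_seq, {"control": CONTROL_REGION, "coding": CODING_REGION}
        if len(ref_seq) >= CONTROL_REGION.start else {},
    )
    hierarchy = (
        HaplogroupHierarchy.from_yaml(config.definitions_yaml)
        if config.definitions_yaml
        else default_hierarchy()
    )
    samples = _read_fasta(config.samples_fasta)
    meta_df = pd.read_csv(config.metadata_tsv, sep="\t", comment="#")
    metadata = {
        str(r["sample"]): {"breed": r["breed"], "country": r["country"],
                           "continent": r["continent"]}
        for _, r in meta_df.iterrows()
    }

    # stage: variant calling
    profiles: List[HaplotypeProfile] = []
    failed: List[str] = []
    for sid in sorted(samples):
        try:
            profiles.append(call_variants(samples[sid], reference, sample_id=sid))
        except Exception:
            failed.append(sid)
    if failed:
        raise PipelineError("variants", "variant calling failed", failed)
    stage_counts["variants"] = len(profiles)
    variants_path = out / "variants.tsv"
    profile_table(profiles).to_csv(variants_path, sep="\t", index=False)

    # stage: classification
    results = [classify(p, hierarchy) for p in profiles]
    stage_counts["classified"] = sum(r.classified for r in results)
    assignments_path = out / "assignments.tsv"
    assignments_table(results).to_csv(assignments_path, sep="\t", index=False)

    # stage: frequency aggregation
    freq = aggregate_frequencies(results, metadata, hierarchy)
    frequencies_path = out / "frequencies.tsv"
    freq.to_tsv(frequencies_path)
    stage_counts["frequency_rows"] = len(freq.counts)

    # stage: parsimony tree over the classified samples
    t1_profiles = [p for p, r in zip(profiles, results) if r.classified]
    outputs = [variants_path, assignments_path, frequencies_path]
    if t1_profiles:
        root_profile = HaplotypeProfile("ancestor", frozenset(),
                                        reference_name=reference.name)
        tree = build_tree(t1_profiles, root_profile,
                          exact_max_haplotypes=config.exact_tree_max)
        tree_path = out / "tree.nwk"
        tree_path.write_text(tree.newick() + "\n")
        edges_path = out / "edges.tsv"
        tree.edge_table().to_csv(edges_path, sep="\t", index=False)
        outputs += [tree_path, edges_path]
        stage_counts["tree_tips"] = tree.n_tips()

        # stage: clade dating (top-level sub-haplogroups with >= 2 samples)
        stats = [clade_stats(tree, tree.root, hierarchy.root,
                             rate_years_per_sub=config.rate_years_per_sub)]
        by_top: Dict[str, List[str]] = {}
        for r in results:
            if r.classified and len(r.path) > 1:
                by_top.setdefault(r.path[1], []).append(r.sample_id)
        for name in sorted(by_top):
            sids = by_top[name]
            if len(sids) < 2:
                continue
            tips = [tree.find_tip(s) for s in sids]
            clade_root = tree.mrca(tips)
            tree.register_clade(name, clade_root)
            stats.append(clade_stats(tree, clade_root, name,
                                     rate_years_per_sub=config.rate_years_per_sub))
        ages_path = out / "clade_ages.tsv"
        stats_table(stats).to_csv(ages_path, sep="\t", index=False)
        outputs.append(ages_path)
        stage_counts["dated_clades"] = len(stats)

    manifest = {
        "package": "bovmito",
        "version": __version__,
        "config": asdict(config),
        "stage_counts": stage_counts,
        "outputs": {p.name: _digest(p) for p in outputs},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunReport(out, manifest, stage_counts)
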