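"""End-to-end drivers: classify -> feature-extract -> align/tree ->
synteny -> correlate, with a machine-readable run manifest.

Each stage writes its outputs under the configured directory and records a
status in the manifest; a missing optional input (e.g. no germline DH
table) marks the dependent stage "missing-input" without failing the run.
Every output header carries the configuration hash, the seed and the pKa
scale, so two runs with identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import io as sio
from . import phylo, stats, synteny
from .classifier import ClassifierConfig, classify
from .records import CuratedReference, ProteinRecord, TailAnnotation


@dataclass(frozen=True)
class RunConfig:
    proteins: str
    references: str
    out_dir: str
    gene_table: str | None = None
    repertoire: str | None = None
    dh_table: str | None = None
    pka_set: str = "bjellqvist"
    identity_floor: float = 0.2
    bootstrap_replicates: int = 100
    synteny_min_block: int = 2
    synteny_anchors: tuple[str, str] = ("MIF", "TOP3B")
    exact_threshold: int = 9
    drop_species: tuple[str, ...] = ("cattle",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "synteny_anchors" in raw:
            raw["synteny_anchors"] = tuple(raw["synteny_anchors"])
        if "drop_species" in raw:
            raw["drop_species"] = tuple(raw["drop_species"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate(self) -> None:
        for name in ("proteins", "references"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path {p!r} does not exist")
        if self.pka_set not in ft.PKA_SETS:
            raise ValueError(f"unknown pKa set {self.pka_set!r}")


def _header(config: RunConfig) -> str:
    return (f"# config={config.digest()} seed={config.seed} "
            f"pka_set={config.pka_set}\n")


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def best_reference(record: ProteinRecord,
                   references: dict[str, CuratedReference],
                   identity_floor: float) -> tuple[str, float] | None:
    """Family reference with the highest alignment identity to the record,
    or None when nothing clears the floor."""
    best: tuple[str, float] | None = None
    for family, ref in sorted(references.items()):
        aln = phylo.global_align(ref.sequence, record.sequence)
        if best is None or aln.identity_columns > best[1]:
            best = (family, aln.identity_columns)
    if best is None or best[1] < identity_floor:
        return None
    return best


def annotate_records(
    records: list[ProteinRecord],
    references: dict[str, CuratedReference],
    pka: ft.PkaSet,
    identity_floor: float = 0.2,
) -> dict[str, TailAnnotation]:
    """Tail annotation per record via its best-aligning family reference."""
    out: dict[str, TailAnnotation] = {}
    for rec in records:
        hit = best_reference(rec, references, identity_floor)
        if hit is None:
            continue
        out[rec.id] = ft.delineate_tail(rec, references[hit[0]], pka=pka,
                                        identity_floor=identity_floor)
    return out


def render_feature_report(records: list[ProteinRecord],
                          annotations: dict[str, TailAnnotation],
                          labels: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Per-species tail table: tail sequence with charged residues marked
    (basic '+', acidic '-'), pI, and length, ordered by clade then species."""
    rows = []
    for rec in records:
        ann = annotations.get(rec.id)
        if ann is None:
            continue
        marked = "".join(
            c + "+" if c in "RKH" else c + "-" if c in "DE" else c
            for c in ann.tail_sequence)
        rows.append({
            "clade": rec.clade, "species": rec.species,
            "gene": (labels or {}).get(rec.id, rec.gene_label),
            "tail_marked": marked, "tail_length": ann.tail_length,
            "n_basic": ann.n_basic, "n_acidic": ann.n_acidic,
            "tail_pi": ann.tail_pi, "full_pi": ann.full_pi,
        })
    cols = ["clade", "species", "gene", "tail_marked", "tail_length",
            "n_basic", "n_acidic", "tail_pi", "full_pi"]
    return (pd.DataFrame(rows, columns=cols)
            .sort_values(["clade", "species", "gene"])
            .reset_index(drop=True))


def assemble_feature_table(records: list[ProteinRecord],
                           annotations: dict[str, TailAnnotation],
                           labels: dict[str, str],
                           cdrh3: pd.DataFrame | None = None,
                           dh: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide per-species table feeding the correlation battery."""
    table: dict[str, dict[str, float]] = {}
    for rec in records:
        ann = annotations.get(rec.id)
        label = labels.get(rec.id, "unknown")
        if ann is None or label not in ("VpreB1", "VpreB2", "IGLL1"):
            continue
        row = table.setdefault(rec.species, {})
        prefix = label.lower()
        row[f"{prefix}_tail_len"] = ann.tail_length
        if ann.tail_pi is not None:
            row[f"{prefix}_tail_pi"] = ann.tail_pi
        if ann.full_pi is not None and label != "IGLL1":
            row[f"{prefix}_full_pi"] = ann.full_pi
    df = pd.DataFrame.from_dict(table, orient="index")
    df.index.name = "species"
    for extra in (cdrh3, dh):
        if extra is not None:
            df = df.join(extra, how="outer")
    for col in stats.FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df.sort_index()[stats.FEATURE_COLUMNS]


STAGE_DEPS = {
    "features": set(),
    "classify": {"features"},
    "tail_report": {"classify"},
    "tree": set(),
    "synteny": set(),
    "correlate": {"classify"},
}


def _closure(stages: set[str] | None) -> set[str]:
    if stages is None:
        return set(STAGE_DEPS)
    out = set(stages)
    changed = True
    while changed:
        changed = False
        for s in list(out):
            missing = STAGE_DEPS[s] - out
            if missing:
                out |= missing
                changed = True
    return out


def run_all(config: RunConfig, stages: set[str] | None = None) -> dict:
    """Execute the requested stages (default: all) in dependency order;
    returns the manifest."""
    config.validate()
    wanted = _closure(stages)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pka = ft.PKA_SETS[config.pka_set]
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "pka_set": config.pka_set,
        "stages": {},
    }

    def done(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}

    records = sio.read_fasta(config.proteins)
    references = sio.read_references(config.references)
    neighborhoods = (synteny.read_gene_table(config.gene_table)
                     if config.gene_table else [])
    context_by_species = {n.species: n for n in neighborhoods}

    annotations: dict[str, TailAnnotation] = {}
    labels: dict[str, str] = {}

    # --- features (tails first: classification consumes them)
    if "features" in wanted:
        annotations = annotate_records(records, references, pka,
                                       config.identity_floor)
        feat = ft.feature_table(records, list(annotations.values()))
        feat_path = out_dir / "features.tsv"
        _write_table(feat, feat_path, config)
        done("features", "success", output=str(feat_path),
             n_annotated=len(annotations))

    # --- classify
    if "classify" in wanted:
        results = [
            classify(rec, tail=annotations.get(rec.id),
                     context=context_by_species.get(rec.species),
                     references=references,
                     config=ClassifierConfig(
                         identity_floor=config.identity_floor))
            for rec in records
        ]
        labels = {r.record_id: r.label for r in results}
        cls_df = pd.DataFrame([{
            "id": r.record_id, "label": r.label, "score": r.score,
            "evidence": ";".join(f"{n}:{s}" for n, s, _ in r.evidence),
        } for r in results])
        cls_path = out_dir / "classification.tsv"
        _write_table(cls_df, cls_path, config)
        with open(out_dir / "classification_evidence.json", "w") as fh:
            json.dump([dataclasses.asdict(r) for r in results], fh, indent=1)
        done("classify", "success", output=str(cls_path),
             labels={lab: sum(1 for v in labels.values() if v == lab)
                     for lab in sorted(set(labels.values()))})

    # --- feature report (tail figure analog)
    if "tail_report" in wanted:
        report = render_feature_report(records, annotations, labels)
        report_path = out_dir / "tail_report.tsv"
        _write_table(report, report_path, config)
        done("tail_report", "success", output=str(report_path))

    # --- align + tree
    if "tree" not in wanted:
        pass
    elif len(records) >= 3:
        ident, ids = phylo.percent_identity_matrix(records)
        ident_df = pd.DataFrame(ident, index=ids, columns=ids)
        ident_path = out_dir / "identity_matrix.tsv"
        _write_table(ident_df, ident_path, config, index=True)
        aligned = _star_alignment(records, references)
        tree = phylo.bootstrap_support(
            [aligned[r.id] for r in records], [r.id for r in records],
            n_replicates=config.bootstrap_replicates, seed=config.seed)
        tree_path = out_dir / "tree.nwk"
        with open(tree_path, "w") as fh:
            fh.write(tree.newick() + "\n")
        done("tree", "success", identity_matrix=str(ident_path),
             tree=str(tree_path), n_replicates=config.bootstrap_replicates)
    else:
        done("tree", "missing-input", reason="fewer than 3 records")

    # --- synteny
    if "synteny" not in wanted:
        pass
    elif len(neighborhoods) >= 2:
        five, three = config.synteny_anchors
        calls = []
        ref_n = neighborhoods[0]
        for other in neighborhoods[1:]:
            try:
                a = synteny.anchored_interval(ref_n, five, three)
                b = synteny.anchored_interval(other, five, three)
            except synteny.AnchorNotFoundError as exc:
                calls.append({"species_pair": [ref_n.species, other.species],
                              "error": f"anchor-not-found:{exc.args[0]}"})
                continue
            call = synteny.shared_blocks(a, b, config.synteny_min_block)
            calls.append({
                "species_pair": list(call.species_pair),
                "blocks": [dataclasses.asdict(blk) for blk in call.blocks],
                "unplaced": {k: list(v) for k, v in call.unplaced.items()},
                "duplications": {k: list(v)
                                 for k, v in call.duplications.items()},
            })
        syn_path = out_dir / "synteny.json"
        with open(syn_path, "w") as fh:
            json.dump(calls, fh, indent=1)
        done("synteny", "success", output=str(syn_path), n_pairs=len(calls))
    else:
        done("synteny", "missing-input", reason="no gene-order table")

    # --- correlate
    if "correlate" not in wanted:
        pass
    elif config.repertoire and config.dh_table:
        reads = sio.read_fasta(config.repertoire)
        cdrh3 = stats.species_cdrh3_summary(reads)[["cdrh3_avg", "cdrh3_max"]]
        dh = sio.read_dh_table(config.dh_table)
        table = assemble_feature_table(records, annotations, labels,
                                       cdrh3, dh)
        table_path = out_dir / "species_features.tsv"
        _write_table(table, table_path, config, index=True)
        battery = stats.correlation_battery(
            table, drop_species=config.drop_species,
            exact_threshold=config.exact_threshold)
        rep = stats.battery_report(battery)
        rep_path = out_dir / "correlations.tsv"
        _write_table(rep, rep_path, config)
        done("correlate", "success", output=str(rep_path),
             n_analyses=len(battery))
    else:
        missing = [n for n, v in (("repertoire", config.repertoire),
                                  ("dh_table", config.dh_table)) if not v]
        done("correlate", "missing-input", reason=",".join(missing))

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _star_alignment(records: list[ProteinRecord],
                    references: dict[str, CuratedReference]
                    ) -> dict[str, str]:
    """Poor-man's common coordinate system: align every record to a single
    pivot (the longest reference) and pad to the union column set.

    Adequate for bootstrap column resampling on closely related inputs;
    deliberately not a progressive multiple alignment.
    """
    pivot = max(references.values(), key=lambda r: len(r.sequence)).sequence \
        if references else records[0].sequence
    cols = len(pivot)
    rows: dict[str, str] = {}
    for rec in records:
        aln = phylo.global_align(pivot, rec.sequence)
        # project record residues onto pivot coordinates; insertions
        # relative to the pivot are dropped
        row = []
        for cp, cq in zip(aln.aligned_query, aln.aligned_subject):
            if cp != "-":
                row.append(cq if cq != "-" else "-")
        row += ["-"] * (cols - len(row))
        rows[rec.id] = "".join(row)
    return rows
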