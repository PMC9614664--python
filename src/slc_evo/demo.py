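"""Bundled synthetic demo dataset for the end-to-end pipeline.

Writes a small, fully synthetic study — five gene families over six
species, gene neighborhoods (one with a planted inversion), a junction
repertoire with an ultralong-CDR-H3 species, a germline DH length table
and matching curated references — plus a ready-to-run YAML config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .pipeline import RunConfig
from .synteny import write_gene_table
from .synthetic import (DEFAULT_FAMILY_SPECS, Edit, NeighborhoodSpec,
                        family_seed, make_family, make_neighborhood,
                        make_repertoire, synthetic_references)

DEMO_SPECIES = ["human", "mouse", "rabbit", "dog", "horse", "cattle"]
DEMO_TREE = ("(((human:0.10,mouse:0.12):0.05,rabbit:0.15):0.05,"
             "((dog:0.10,horse:0.10):0.03,cattle:0.14):0.05);")

_NEIGHBOR_GENES = (
    ("MIF", "+"), ("SLC2A11", "+"), ("VPREB1", "-"), ("IGLL1", "-"),
    ("TOP3B", "+"), ("VPREB3", "+"), ("ZNF70", "-"), ("SLC5A1", "+"),
    ("SLC5A4", "+"), ("VPREB2", "-"), ("IGL", "+"), ("ZNF280A", "-"),
)


def simulate_demo(out_dir: str | Path, seed: int = 7) -> Path:
    """Generate the demo inputs under ``out_dir``; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = []
    for label, spec in DEFAULT_FAMILY_SPECS.items():
        fam, _ = make_family(spec, DEMO_TREE, family_seed(label, seed))
        records.extend(fam)
    records.sort(key=lambda r: r.id)
    sio.write_fasta(records, out / "proteins.fasta")
    sio.write_references(synthetic_references(seed), out / "references.tsv")

    neighborhoods = []
    for i, species in enumerate(DEMO_SPECIES):
        edits = (Edit(kind="inversion", span=(5, 8)),) if species == "cattle" \
            else ()
        spec = NeighborhoodSpec(gene_order=_NEIGHBOR_GENES,
                                anchors=("MIF", "TOP3B"), edits=edits,
                                species=species)
        _, edited, _ = make_neighborhood(spec, seed + i)
        neighborhoods.append(edited)
    write_gene_table(neighborhoods, out / "gene_table.tsv")

    rng = np.random.default_rng(seed)
    lengths = {
        sp: sorted(int(x) for x in rng.integers(8, 17, size=12))
        for sp in DEMO_SPECIES
    }
    # the ultralong lineage: a subset of very long CDR H3 reads
    lengths["cattle"] = sorted(
        lengths["cattle"][:8] + [int(x) for x in rng.integers(40, 61, size=4)])
    reads, _ = make_repertoire(lengths, seed)
    sio.write_fasta(reads, out / "repertoire.fasta")

    dh_max = {sp: 3 * max(lengths[sp]) - 10 for sp in DEMO_SPECIES}
    with open(out / "dh_table.tsv", "w") as fh:
        fh.write("species\tdh_avg\tdh_max\n")
        for sp in DEMO_SPECIES:
            fh.write(f"{sp}\t{dh_max[sp] * 0.6:.1f}\t{dh_max[sp]}\n")

    config = RunConfig(
        proteins=str(out / "proteins.fasta"),
        references=str(out / "references.tsv"),
        gene_table=str(out / "gene_table.tsv"),
        repertoire=str(out / "repertoire.fasta"),
        dh_table=str(out / "dh_table.tsv"),
        out_dir=str(out / "results"),
        bootstrap_replicates=25,
        seed=seed,
    )
    cfg_path = out / "config.yaml"
    payload = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in config.__dict__.items()}
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return cfg_path
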