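"""On-disk dataset layout and loaders.

A dataset directory holds everything one analysis consumes:

```
dataset/
  species_tree.nwk     rooted singly-labelled species tree
  polyploids.txt       one polyploid species code per line
  trees/<family>.nwk   one rooted gene tree per family
  alignments/<family>.fasta   in-frame codon alignment per family
  mito.tsv             species_a  species_b  T_mt  low  high   (Mya)
  mask.txt             optional: family ids excluded by a conversion screen
  truth.json           optional: simulator ground truth
```

Plain text only; FASTA through Biopython, trees through the package's
Newick layer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inference import MitoDivergence
from .model import PipelineConfig, PolyploidyHistory
from .simulate import SimulatedDataset
from .trees import GeneTree, SpeciesTree, read_newick

__all__ = ["write_dataset", "load_dataset", "load_model"]


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> Path:
    """Write a simulated dataset to the directory layout above."""
    out = Path(outdir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "species_tree.nwk").write_text(data.history.species_tree.to_newick() + "\n")
    (out / "polyploids.txt").write_text(
        "\n".join(sorted(data.scenario.polyploid_species)) + "\n"
    )
    for i, (tree, aln) in enumerate(zip(data.gene_trees, data.alignments)):
        fam = f"fam{i:04d}"
        (out / "trees" / f"{fam}.nwk").write_text(tree.to_newick() + "\n")
        records = [
            SeqRecord(Seq(seq), id=label, description="")
            for label, seq in sorted(aln.items())
        ]
        SeqIO.write(records, out / "alignments" / f"{fam}.fasta", "fasta")
    mito = pd.DataFrame(
        [
            {
                "species_a": m.pair[0],
                "species_b": m.pair[1],
                "T_mt": m.T_mt,
                "low": m.low,
                "high": m.high,
            }
            for m in data.mito
        ]
    )
    mito.to_csv(out / "mito.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(data.truth, indent=2) + "\n")
    return out


def load_dataset(path: str | Path) -> dict:
    """Load a dataset directory into in-memory components."""
    path = Path(path)
    stree_file = path / "species_tree.nwk"
    if not stree_file.exists():
        raise FileNotFoundError(f"missing {stree_file}")
    species_tree = read_newick(stree_file.read_text().strip(), kind="species")
    polyploids = [
        line.strip()
        for line in (path / "polyploids.txt").read_text().splitlines()
        if line.strip()
    ]
    gene_trees: dict[str, GeneTree] = {}
    for f in sorted((path / "trees").glob("*.nwk")):
        gene_trees[f.stem] = read_newick(
            f.read_text().strip(), kind="gene", allow_multifurcations=True
        )
    alignments: dict[str, dict[str, str]] = {}
    aln_dir = path / "alignments"
    if aln_dir.is_dir():
        for f in sorted(aln_dir.glob("*.fasta")):
            alignments[f.stem] = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(f, "fasta")
            }
    mito = []
    mito_file = path / "mito.tsv"
    if mito_file.exists():
        df = pd.read_csv(mito_file, sep="\t")
        for row in df.itertuples():
            mito.append(
                MitoDivergence(
                    pair=(str(row.species_a), str(row.species_b)),
                    T_mt=float(row.T_mt),
                    low=None if pd.isna(row.low) else float(row.low),
                    high=None if pd.isna(row.high) else float(row.high),
                )
            )
    mask_file = path / "mask.txt"
    mask = (
        [l.strip() for l in mask_file.read_text().splitlines() if l.strip()]
        if mask_file.exists()
        else []
    )
    truth_file = path / "truth.json"
    truth = json.loads(truth_file.read_text()) if truth_file.exists() else None
    return {
        "gene_trees": gene_trees,
        "species_tree": species_tree,
        "polyploid_species": polyploids,
        "alignments": alignments,
        "mito": mito,
        "conversion_mask": mask,
        "truth": truth,
    }


def load_model(path: str | Path, config: PipelineConfig | None = None) -> PolyploidyHistory:
    parts = load_dataset(path)
    truth = parts.pop("truth")
    model = PolyploidyHistory(config=config, **parts)
    if truth is not None:
        model.truth = truth
    return model
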