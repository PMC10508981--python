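"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython; GFF3 lines are emitted directly (1-based
inclusive coordinates); tables are TSV via pandas.  The profile library is
stored as one aligned FASTA per domain plus a catalytic-position TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import DomainProfile, ElementChain, build_pssm, completeness_score
from .structure import StructureCall
from .synth import DomainSpec, GenomeRecord, PlantedTruth


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_genomes(path: str | Path, taxon_map: dict[str, str] | None = None) -> list[GenomeRecord]:
    taxon_map = taxon_map or {}
    return [
        GenomeRecord(genome_id=rec.id, sequence=str(rec.seq).upper(), taxon=taxon_map.get(rec.id, ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genomes(genomes: list[GenomeRecord], path: str | Path) -> None:
    write_fasta([(g.genome_id, g.sequence) for g in genomes], path)


# ---------------------------------------------------------------------------
# ground truth

def write_truth_gff3(truths: list[PlantedTruth], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for t in truths:
        attrs = f"ID={t.element_id};structure={t.structure};rh_core={t.rh_core_state}"
        if t.arh_core_states:
            attrs += ";arh_cores=" + ",".join(t.arh_core_states)
        lines.append(
            "\t".join(
                [t.genome_id, "ltrarch_sim", "LTR_retrotransposon",
                 str(t.span[0] + 1), str(t.span[1]), ".", t.strand, ".", attrs]
            )
        )
        for i, sp in enumerate(t.ltr_spans):
            lines.append(
                "\t".join(
                    [t.genome_id, "ltrarch_sim", "long_terminal_repeat",
                     str(sp[0] + 1), str(sp[1]), ".", t.strand, ".",
                     f"ID={t.element_id}.ltr{i};Parent={t.element_id}"]
                )
            )
        for j, (name, sp) in enumerate(t.domain_spans):
            lines.append(
                "\t".join(
                    [t.genome_id, "ltrarch_sim", "protein_match",
                     str(sp[0] + 1), str(sp[1]), ".", t.strand, ".",
                     f"ID={t.element_id}.d{j};Parent={t.element_id};Name={name}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_tsv(truths: list[PlantedTruth], path: str | Path) -> None:
    rows = [
        {
            "element_id": t.element_id,
            "genome_id": t.genome_id,
            "start": t.span[0],
            "end": t.span[1],
            "strand": t.strand,
            "structure": t.structure,
            "rh_core_state": t.rh_core_state,
            "arh_core_states": ",".join(t.arh_core_states),
            "domain_order": ",".join(n for n, _ in t.domain_spans),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# profile library

def write_profile_library(library: list[DomainSpec], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cat_rows = []
    for spec in library:
        write_fasta([(f"{spec.name}_consensus", spec.consensus)], out / f"{spec.name}.fasta")
        for idx, res in spec.catalytic_positions:
            cat_rows.append({"domain": spec.name, "position": idx, "residue": res})
    pd.DataFrame(cat_rows, columns=["domain", "position", "residue"]).to_csv(
        out / "catalytic_positions.tsv", sep="\t", index=False
    )


def read_profile_library(profiles_dir: str | Path, pseudocount: float = 1.0) -> list[DomainProfile]:
    """Build PSSMs from per-domain FASTA alignments and the catalytic TSV."""
    pdir = Path(profiles_dir)
    cat_path = pdir / "catalytic_positions.tsv"
    cat: dict[str, list[tuple[int, str]]] = {}
    if cat_path.exists():
        df = pd.read_csv(cat_path, sep="\t")
        for _, row in df.iterrows():
            cat.setdefault(row["domain"], []).append((int(row["position"]), row["residue"]))
    profiles = []
    for fa in sorted(pdir.glob("*.fasta")):
        name = fa.stem
        rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(fa), "fasta")]
        profiles.append(
            build_pssm(rows, pseudocount=pseudocount, name=name,
                       catalytic_positions=tuple(cat.get(name, [])))
        )
    return profiles


# ---------------------------------------------------------------------------
# annotation outputs

def write_chain_gff3(
    genome_calls: list[tuple[ElementChain, StructureCall | None]], path: str | Path
) -> None:
    lines = ["##gff-version 3"]
    for chain, call in genome_calls:
        s, e = chain.full_span
        attrs = f"ID={chain.chain_id}"
        if call is not None:
            attrs += f";structure={call.label}"
        if chain.ltr is not None:
            attrs += f";ltr_identity={chain.ltr.identity:.1f};ltr_length={chain.ltr.length}"
        if chain.edge_truncated:
            attrs += ";edge_truncated=true"
        lines.append(
            "\t".join([chain.genome_id, "ltrarch", "LTR_retrotransposon",
                       str(s + 1), str(e), ".", chain.strand, ".", attrs])
        )
        if chain.ltr is not None:
            for i, sp in enumerate((chain.ltr.span5, chain.ltr.span3)):
                lines.append(
                    "\t".join([chain.genome_id, "ltrarch", "long_terminal_repeat",
                               str(sp[0] + 1), str(sp[1]), ".", chain.strand, ".",
                               f"ID={chain.chain_id}.ltr{i};Parent={chain.chain_id}"])
                )
        for k, h in enumerate(chain.hits):
            lines.append(
                "\t".join([chain.genome_id, "ltrarch", "protein_match",
                           str(h.span[0] + 1), str(h.span[1]), f"{h.score:.2f}",
                           chain.strand, ".",
                           f"ID={chain.chain_id}.d{k};Parent={chain.chain_id};Name={h.profile_name}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_chain_tsv(
    genome_calls: list[tuple[ElementChain, StructureCall | None]], path: str | Path
) -> None:
    rows = []
    for chain, call in genome_calls:
        rows.append(
            {
                "chain_id": chain.chain_id,
                "genome_id": chain.genome_id,
                "start": chain.span[0],
                "end": chain.span[1],
                "strand": chain.strand,
                "domain_order": ",".join(chain.domain_order()),
                "orf_index": ",".join("." if i is None else str(i) for i in chain.orf_index),
                "structure": call.label if call else "",
                "rationale": call.rationale if call else "",
                "ltr_identity": f"{chain.ltr.identity:.2f}" if chain.ltr else "",
                "ltr_length": chain.ltr.length if chain.ltr else "",
                "edge_truncated": chain.edge_truncated,
                "completeness": f"{completeness_score(chain):.3f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_domain_fasta(chains: list[ElementChain], path: str | Path) -> None:
    """Translated domain sequences, headers elementID|domain|genome|span|strand."""
    records = []
    for chain in chains:
        for h in chain.hits:
            header = f"{chain.chain_id}|{h.profile_name}|{h.genome_id}|{h.span[0]}-{h.span[1]}|{h.strand}"
            records.append((header, h.matched_aa))
    write_fasta(records, path)


def read_domain_fasta(path: str | Path) -> list[dict]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chain_id, domain, genome_id, span, strand = rec.id.split("|")
        s, e = span.split("-")
        out.append(
            {"chain_id": chain_id, "domain": domain, "genome_id": genome_id,
             "start": int(s), "end": int(e), "strand": strand, "seq": str(rec.seq)}
        )
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
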