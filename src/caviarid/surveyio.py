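"""Plain-text survey input/output.

A survey on disk is a lot table (TSV), an egg manifest (TSV recording which
markers were attempted per egg and whether they amplified), and one FASTA of
egg sequences keyed ``lotid_eggindex_marker``.  Results are written as a TSV
table plus a human-readable per-lot report.
"""

from __future__ import annotations

import pathlib

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refdb import parse_label
from .workflow import EggRecord, Lot


def write_survey(lots, outdir) -> None:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{"lot_id": lot.lot_id, "label": lot.label.raw,
             "channel": lot.channel, "year": lot.year,
             "price_per_oz": lot.price_per_oz} for lot in lots]
    pd.DataFrame(rows).to_csv(out / "lots.tsv", sep="\t", index=False)
    manifest, records = [], []
    for lot in lots:
        for egg in lot.eggs:
            for marker, seq in egg.outcomes.items():
                status = "ok" if seq else "failed"
                manifest.append({"lot_id": lot.lot_id,
                                 "egg_index": egg.egg_index,
                                 "marker": marker, "status": status})
                if seq:
                    key = f"{lot.lot_id}_{egg.egg_index}_{marker}"
                    records.append(SeqRecord(Seq(seq), id=key, description=""))
    pd.DataFrame(manifest).to_csv(out / "eggs.tsv", sep="\t", index=False)
    SeqIO.write(records, str(out / "eggs.fasta"), "fasta")


def read_survey(indir) -> list[Lot]:
    ind = pathlib.Path(indir)
    lot_df = pd.read_csv(ind / "lots.tsv", sep="\t", dtype={"lot_id": str})
    egg_df = pd.read_csv(ind / "eggs.tsv", sep="\t", dtype={"lot_id": str})
    seqs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(ind / "eggs.fasta"), "fasta")}
    lots = []
    for _, row in lot_df.iterrows():
        sub = egg_df[egg_df.lot_id == row.lot_id]
        eggs = []
        for egg_index, grp in sub.groupby("egg_index"):
            outcomes = {}
            for _, erow in grp.iterrows():
                key = f"{row.lot_id}_{egg_index}_{erow.marker}"
                outcomes[erow.marker] = (seqs.get(key)
                                         if erow.status == "ok" else None)
            eggs.append(EggRecord(lot_id=row.lot_id, egg_index=int(egg_index),
                                  outcomes=outcomes))
        price = None if pd.isna(row.get("price_per_oz")) else \
            float(row.price_per_oz)
        lots.append(Lot(lot_id=row.lot_id, label=parse_label(row.label),
                        channel=row.channel, year=int(row.year),
                        eggs=sorted(eggs, key=lambda e: e.egg_index),
                        price_per_oz=price))
    return lots


def results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "lot_id": r.lot_id, "verdict": r.verdict,
            "call": r.final_call.display if r.final_call else "",
            "markers_used": "+".join(r.markers_used),
            "n_eggs_tested": r.n_eggs_tested,
            "n_haplotypes": r.n_haplotypes,
            "confirmation": r.confirmation,
            "channel": r.channel, "year": r.year,
            "top_identity": (round(r.final_call.top_identity, 2)
                             if r.final_call and r.final_call.top_identity
                             is not None else ""),
            "notes": "; ".join(r.notes),
        })
    return pd.DataFrame(rows)


def write_results(results, outdir) -> None:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(out / "lot_results.tsv", sep="\t",
                                  index=False)
    with open(out / "lot_reports.txt", "w") as fh:
        for r in results:
            fh.write(f"lot {r.lot_id}: {r.verdict}\n")
            if r.final_call is not None:
                fh.write(f"  call: {r.final_call.display} "
                         f"(markers {'+'.join(r.markers_used)})\n")
            fh.write(f"  eggs tested: {r.n_eggs_tested}, "
                     f"haplotypes: {r.n_haplotypes}, "
                     f"confirmation: {r.confirmation}\n")
            for note in r.notes:
                fh.write(f"  note: {note}\n")


def summary_text(summary, by_channel=None) -> str:
    lines = [
        f"lots surveyed:        {summary.n_lots}",
        f"testable lots:        {summary.n_testable}",
        f"mislabeled lots:      {summary.n_mislabeled}"
        + (f" (of which mixed: {summary.n_mixed})" if summary.n_mixed else ""),
        f"mislabeling rate:     {summary.rate_percent:.1f}%",
        f"exact 95% CI:         [{summary.ci_low_percent:.1f}%, "
        f"{summary.ci_high_percent:.1f}%]",
    ]
    if by_channel:
        lines.append("by channel:")
        for ch, s in by_channel.items():
            lines.append(f"  {ch}: {s.n_mislabeled}/{s.n_testable} "
                         f"({s.rate_percent:.1f}%)")
    return "\n".join(lines)
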