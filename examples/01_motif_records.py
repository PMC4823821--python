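"""Motif records: nomenclature normalization, distinctness, querying.

Builds a tiny record table, renames an aliased gene to its official
name, deduplicates on the (motif, RBP, experiment, organism) rule and
runs a synonym query.
"""

from rbpkit import (
    MotifRecord,
    QueryCriteria,
    SynonymTable,
    distinct_entries,
    normalize_record,
    query,
)

table = SynonymTable()
table.add("Homo sapiens", "CUGBP1", "CELF1")
table.add("Homo sapiens", "SFRS1", "SRSF1")

raw = [
    # same motif, two different RBPs: stays two distinct entries.
    # SFRS1 is an alias; normalization renames it to SRSF1
    MotifRecord(gene_name="SFRS1", motif="ACGCGCC", organism="Homo sapiens",
                experiment="SELEX", gene_id="ENSG00000136450"),
    MotifRecord(gene_name="RBM8A", motif="ACGCGCC", organism="Homo sapiens",
                experiment="SELEX"),
    # alias + DNA-alphabet motif: both normalised at ingestion
    MotifRecord(gene_name="CUGBP1", motif="tgtgtg", organism="Homo sapiens",
                experiment="EMSA"),
    # duplicates the first record once both carry the official name: dropped
    MotifRecord(gene_name="SRSF1", motif="ACGCGCC", organism="Homo sapiens",
                experiment="SELEX", gene_id="ENSG00000136450"),
]

records = [normalize_record(r, table) for r in raw]
records = distinct_entries(records)

print(f"{len(raw)} raw rows -> {len(records)} distinct entries")
for r in records:
    print(f"  {r.gene_name:6s} {r.motif:8s} {r.experiment:6s} synonyms={r.synonyms}")

hits = query(records, QueryCriteria(synonym="SFRS1"))
print(f"query synonym=SFRS1 -> {[r.gene_name for r in hits]}")
# The duplicate row collapsed, ACGCGCC kept one entry per RBP, and the
# CUGBP1 alias now lives in CELF1's synonym list.
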