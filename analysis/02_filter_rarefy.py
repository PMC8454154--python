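"""Global preprocessing: min-count OTU filter, then rarefaction.

OTUs with fewer than 100 reads across all samples (soils and animals) are
removed, then every sample is rarefied to 13,551 reads; samples below that
depth are discarded and listed.  Writes the rarefied table under
results/rarefied/.
"""

from pathlib import Path

from trophoweb import io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20170102


def main() -> None:
    table = io.read_otu_table(BASE / "synthetic_study" / "otu_table.tsv")
    before = table.n_otus
    table = io.filter_low_count_otus(table, min_total=100)
    print(f"min-count filter: {before} -> {table.n_otus} OTUs")
    table, discarded = io.rarefy(table, depth=13551, seed=SEED)
    print(f"rarefaction to 13,551: kept {table.n_samples} samples, discarded {len(discarded)}")
    if discarded:
        print("  discarded:", ", ".join(discarded))
    out = BASE / "rarefied"
    out.mkdir(parents=True, exist_ok=True)
    io.write_otu_table(table, out / "otu_table.tsv")
    meta = io.read_metadata(BASE / "synthetic_study" / "metadata.tsv")
    io.write_metadata(io.SampleMetadata(meta.frame.loc[table.sample_ids].copy()), out / "metadata.tsv")


if __name__ == "__main__":
    main()
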