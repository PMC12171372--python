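"""Build, curate and serialize a population STR allele-frequency table.

Synthesizes a 21-locus table, drops rare alleles at the 0.002 curation
threshold, and round-trips the result through the canonical CSV dialect.
"""

from pathlib import Path

from strkin import (
    filter_rare_alleles,
    normalize_frequencies,
    read_frequency_table,
    synth_frequency_table,
    write_frequency_table,
)

table = normalize_frequencies(synth_frequency_table(21, 10, 1.0, seed=7))
print(f"synthetic table: {len(table)} loci, {table.n_alleles} allele rows")

filtered = filter_rare_alleles(table, max_excluded=0.002)
print(f"after rare-allele curation: {filtered.n_alleles} alleles remain")
# alleles at frequency <= 0.002 are deleted and each locus renormalized,
# mirroring how low-diversity population tables are prepared for simulation

out = Path("scratch_table.csv")
write_frequency_table(filtered, out)
back = read_frequency_table(out, "demo")
print(f"round-trip through {out}: {back.n_alleles} alleles, "
      f"normalized={back.is_normalized}")
out.unlink()
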