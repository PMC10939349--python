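"""Extract a 10-kb gene neighborhood and screen it for HGT context.

A target gene's window spans 10 kb up- and downstream of its
boundaries; any gene overlapping the window by one base pair or more is
part of the neighborhood.  The screen flags a site-specific DNA
recombinase (K06400) upstream and Type IV pilus assembly proteins
(K02662/K02664) downstream — the mobilization pattern observed around
horizontally transferred sporulation genes.
"""

from pathlib import Path

from archannot import GeneratorConfig, generate_dataset, io
from archannot.synteny import extract_flank_window, flag_hgt_context, \
    synteny_table

out = Path("scratch/example_bundle")
generate_dataset(GeneratorConfig(seed=7), out)
genes = io.read_gene_features(out / "genes.gff3", out / "gene_ko.tsv")

window = extract_flank_window(genes, "tgt_spoVA")
print(f"window [{window.window_start}, {window.window_end}] holds "
      f"{len(window.flank_genes)} genes")

flags = flag_hgt_context(window)
print(f"upstream recombinase: {flags.upstream_recombinase}")
print(f"downstream pilus:     {flags.downstream_pilus}")
print(f"motif matches (gene, KO, offset): {flags.matches}")
# The planted K02664 copy sits 12 kb downstream, outside the window,
# so it correctly does not contribute to the downstream flag.

print(synteny_table([window]).to_string(index=False))
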