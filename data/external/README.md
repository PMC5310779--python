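# External sequence panel (user-supplied)

The external-data acceptance tests re-measure published per-gene statistics
on the real symbiont sequence panel, which is not distributed with this
package.  To run them, fetch the deposited sequences by accession from
DDBJ/EMBL/GenBank and place them here as:

- `groES_Vok.fa` — the groES gene of the *Phreagena okutanii* symbiont
  (Vok), plain FASTA, one record.
- `genes.fa` — all panel genes, headers `symbiont_id|gene_id`.
- `meta.tsv` — columns `symbiont_id`, `gene_id`, `clade` (I/II/outgroup),
  `status` (intact/degraded/absent).
- `aln/<gene_id>.fa` — one alignment FASTA per gene including the outgroup
  (Bsep_S) row.

Without these files the corresponding tests fail with a message saying the
panel is absent; all other tests are self-contained.
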