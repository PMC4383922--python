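"""Scan a user target sequence against a species miRNome.

The reverse workflow of scan_custom_mirna.py: every miRNA of the chosen
species is screened for seed complementarity inside one submitted target
sequence (a 3'-UTR, or unconventionally a coding region or 5'-UTR).
"""

import tempfile

from mirfunc import mirbase_io, seedscan
from mirfunc.sequence import revcomp_rna
from mirfunc.synthetic_fixtures import FixtureSpec, generate

with tempfile.TemporaryDirectory() as tmp:
    fx = generate(FixtureSpec(rng_seed=7), tmp)
    mirnome = mirbase_io.read_mature_fasta(fx.mature_fasta, species_filter="hsa")

# build a 400-nt target carrying seed complements of two known miRNAs
planted = [mirnome[0], mirnome[3]]
filler = "AGCUGCAUCG" * 40
target = filler[:120]
for mat in planted:
    target += revcomp_rna(seedscan.seed_of(mat.sequence)) + filler[:120]

result = seedscan.scan_custom_target(target, mirnome, target_id="my-utr", species="hsa")
print(f"{len(result.rows)} of {len(mirnome)} hsa miRNAs have a seed site in the target")
print("rank  score  miRNA                 sites")
for row in result.rows:
    positions = ";".join(f"{s.start + 1}-{s.end}" for s in row.sites)
    print(f"{row.rank:>4}  {row.score:>5}  {row.mirna_name:<20}  {positions}")
print("planted:", ", ".join(m.name for m in planted))
# The planted miRNAs must appear among the rows; any extra rows are
# incidental 7-mer matches arising from the filler sequence.
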