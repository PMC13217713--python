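"""Load a molecule table, canonicalize SMILES, and train a BPE tokenizer.

Builds a small CSV in a temp directory, loads it with missing-label
masking, then trains a byte-level BPE tokenizer on the fixture corpus
and shows the lossless encode/decode round trip.
"""

import tempfile
from pathlib import Path

from molfuse import (FixtureSpec, canonicalize_smiles, decode, encode,
                     gen_molecule_dataset, load_molecule_table, mlm_mask,
                     train_bpe)

print("canonicalize('OCC') ->", canonicalize_smiles("OCC"))  # CCO

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "toy.csv"
    path.write_text("smiles,endpoint_a,endpoint_b\n"
                    "OCC,1,0\n"
                    "CCN,,1\n"       # missing cell -> observed=False
                    "C(,1,1\n"       # invalid SMILES -> dropped
                    "c1ccccc1,0,\n")
    records, dropped = load_molecule_table(str(path), "smiles",
                                           ["endpoint_a", "endpoint_b"])
    print(f"loaded {len(records)} records, dropped {dropped} invalid row(s)")
    for r in records:
        print(f"  {r.smiles:12s} labels={r.labels} observed={r.observed}")

# a tokenizer trained on a synthetic fragment-grammar corpus
recs, _ = gen_molecule_dataset(FixtureSpec(n=200, n_endpoints=2,
                                           positive_rates=(0.5, 0.5), seed=0))
tok = train_bpe([r.smiles for r in recs], vocab_limit=4 + 256 + 16,
                min_pair_freq=2)
print(f"\ntokenizer: vocab {tok.vocab_size}, merges "
      f"{[ (tok.id_to_bytes[n]).decode() for _, _, n in tok.merges ]}")

s = recs[0].smiles
ts = encode(s, tok, max_len=32)
print(f"encode({s!r}): {int(ts.n_real)} real tokens of 32 slots")
print("round trip ok:", decode(ts, tok) == s)

masked, targets, tmask = mlm_mask([ts], rate=0.15, rng_seed=0)
print(f"MLM masking at 15%: {int(tmask.sum())} position(s) masked "
      f"(of {int((ts.ids >= 4).sum())} maskable)")
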