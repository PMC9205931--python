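"""Per-epoch augmentation: substitutions, indels and raw-read decoration."""

import numpy as np

from ednacnn import AugmentConfig, simulate_reference_db
from ednacnn.augment import decorate, make_epoch_batch, substitute

rng = np.random.default_rng(0)
db, _ = simulate_reference_db(n_species=5, seqs_per_species_range=(1, 3), seed=0)
print(f"reference DB: {len(db)} records, {db.n_classes} species")

seq = db.records[0].sequence
mutated = substitute(seq, 0.05, rng)
n_changed = sum(a != b for a, b in zip(seq, mutated))
print(f"5% substitution pass changed {n_changed}/{len(seq)} positions")

cfg = AugmentConfig.training(decorate=True, add_reverse_complements=True)
decorated = decorate(seq, cfg.forward_primer, cfg.reverse_primer, cfg.n_prefix_len)
print(f"decorated read template ({len(decorated)} bp): {decorated[:40]}...")
# 10 N placeholders (tag + attachment bases), then the forward primer, the
# amplicon, the reverse complement of the reverse primer, and 10 more Ns.

X, y = make_epoch_batch(db, cfg, rng)
print(f"epoch batch: X {X.shape} (reverse complements double the batch), "
      f"{len(np.unique(y))} classes")
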