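"""Build and apply a replacement plan on a tiny hand-made corpus.

'measure' and '13' are the most frequent members of their synonym pools,
so the rare variants amount/bill/step and thirteen/xiii collapse onto
them; words whose pools are entirely rare are retained.
"""

from synnorm import (
    Corpus,
    apply_replacement,
    build_replacement_plan,
    count_frequencies,
    default_threshold,
)
from synnorm.synonyms import FixtureSynonyms, default_fixture_path

resource = FixtureSynonyms.from_tsv(default_fixture_path())
corpus = Corpus(
    [
        ["measure"] * 10 + ["13"] * 8,
        ["amount", "bill", "step", "thirteen", "xiii"],
        ["peregrinate", "recondite"],  # pools entirely rare: retained
    ]
)

freq = count_frequencies(corpus)
tau = default_threshold(freq, multiplier=1.0)
print(f"total tokens {freq.total_tokens}, vocabulary {freq.vocab_size}, "
      f"mean per-type frequency mu = {freq.mean_frequency:.2f}, tau = {tau:.2f}")

plan = build_replacement_plan(freq, resource, tau)
print(f"candidates below tau: {plan.n_candidates}; replaced: {plan.n_replaced}; "
      f"retained (all synonyms rare): {plan.n_retained_all_infrequent}")
for src, tgt in sorted(plan.mapping.items()):
    print(f"  {src} -> {tgt}   (f={freq[src]} -> f={freq[tgt]})")

out = apply_replacement(corpus, plan)
print("document 2 before:", corpus.documents[1])
print("document 2 after: ", out.documents[1])
# Every rare variant now reads as its dominant synonym; token counts are
# unchanged, only the vocabulary shrank.
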