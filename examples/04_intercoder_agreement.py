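"""Average pairwise percent agreement between independent coders.

Three coders label the same pilot items; for each unordered pair of coders
we take the percentage of identically labeled items, then average over the
three pairs.
"""

from forumminer import LabelMatrix, average_pairwise_percent_agreement

items = tuple(f"post{i}" for i in range(8))
coders = ("coder1", "coder2", "coder3")
rows = [
    ("Negative", "Negative", "Negative"),
    ("Negative", "Negative", "Neutral"),
    ("Neutral", "Neutral", "Neutral"),
    ("Positive", "Positive", "Positive"),
    ("Neutral", "Negative", "Neutral"),
    ("Negative", "Negative", "Negative"),
    ("Positive", "Neutral", "Positive"),
    ("Neutral", "Neutral", "Neutral"),
]
matrix = LabelMatrix(
    items=items,
    coders=coders,
    labels={(item, coder): rows[k][j]
            for k, item in enumerate(items)
            for j, coder in enumerate(coders)},
)
score = average_pairwise_percent_agreement(matrix)
print(f"{len(items)} items, {len(coders)} coders")
print(f"average pairwise percent agreement: {score:.2f}%")
# 100% would mean unanimity; values above ~80% are commonly taken as good
# enough to split the remaining labeling work between coders.
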