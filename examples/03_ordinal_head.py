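"""The ordinal mechanics, end to end on paper values.

Shows the cumulative encoding of the four critical values, the recovery of
class probabilities from cumulative probabilities, the prediction rule, and
the multi-task binary cross-entropy.
"""

import numpy as np

from cardiov import (
    class_probs,
    cumulative_probs,
    encode_cumulative,
    ordinal_loss,
    predict,
)

print("cumulative targets (is value > no / low / medium risk?):")
for v in range(4):
    print(f"  value {v} -> y = {encode_cumulative(v).astype(int)}")

z = np.array([2.0, 0.5, -3.0])  # logits from the network's three tasks
p = cumulative_probs(z)
q = class_probs(p)
print(f"\nlogits z = {z}")
print(f"cumulative probs p = sigmoid(z) = {np.round(p, 3)}")
print(f"class probs q = (1-p0, p0-p1, p1-p2, p2) = {np.round(q, 3)} "
      f"(sum {q.sum():.3f})")
print(f"predicted critical value = argmax q = {predict(z)}")

y = encode_cumulative(2)
print(f"\nloss against true value 2 (y={y.astype(int)}): "
      f"{ordinal_loss(p, y):.4f} nats "
      f"(an uninformative p=0.5 costs {np.log(2):.4f})")
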