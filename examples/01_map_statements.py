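"""Map SCP-ECG statement codes to critical values.

Loads the packaged 71-code mapping, looks up a few individual statements,
and labels multi-statement records with the maximum rule.
"""

import pandas as pd

from cardiov import label_dataset, load_mapping, record_value, statement_to_value

table = load_mapping()
print(f"mapping covers {len(table)} statement codes; "
      f"codes per critical value: {table.class_sizes()}")

for code in ("NORM", "STACH", "AF", "IMI"):
    print(f"  {code:6s} -> critical value {statement_to_value(code, table)}")

# a record is labeled by its highest-risk statement, so a normal rhythm
# annotation never hides a co-occurring infarction
print("record {NORM, SR}  ->", record_value({"NORM", "SR"}, table))
print("record {NORM, IMI} ->", record_value({"NORM", "IMI"}, table))

metadata = pd.DataFrame({
    "scp_codes": ["{'NORM': 100.0, 'SR': 0.0}",
                  "{'SBRAD': 100.0}",
                  "{'AF': 100.0, 'PVC': 50.0}",
                  "{'WPW': 100.0, 'NORM': 10.0}"],
}, index=[1, 2, 3, 4])
labels, counts, _ = label_dataset(metadata, table)
print("labeled toy records:", labels.to_dict(), "class counts:", counts)
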