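"""Summarize the expert-panel agreement scores from the clinical validation.

Seven dieticians rated their agreement (1-5) with the system's
recommendation for five patient profiles. Per-profile mean and sample SD,
then the overall mean/SD across the five profile means: profile FG (a
patient with second-degree obesity) scores lowest at 3.29, the overall
mean is 4.23.
"""

import json

import nutricopd as nc

table = nc.load_validation_agreement()
summary = nc.summarize_agreement(table)
print(json.dumps(summary, indent=2))
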