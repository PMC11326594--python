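"""Recompute the published worked examples from their raw counts.

Run:  python examples/05_verify_published_tables.py
"""

from folliscan import verify_reference_tables
from folliscan.pipeline import format_table_checks

print(format_table_checks(verify_reference_tables()))
print(
    "\nEach line recomputes a published accuracy, FDR/FOR or cohort percent\n"
    "difference from the raw confusion counts / group means with this\n"
    "package's metric code; INFO rows are known inconsistencies in the source."
)
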