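"""ADME screening: keep compounds with OB >= 30% and DL >= 0.18.

Loads the bundled table of 11 published active ingredients of Prunella
vulgaris and shows that all of them clear the screen, then tightens the
thresholds to show the screen is monotone.
"""

from herbnet import AdmeCriteria, CompoundRecord, filter_compounds
from herbnet.reference import load_active_compounds

records = [CompoundRecord(r.compound_id, r.name, r.ob, r.dl)
           for r in load_active_compounds().itertuples(index=False)]

active, rejected = filter_compounds(records)
print(f"default screen (OB>=30, DL>=0.18): {len(active)} active, {len(rejected)} rejected")

strict, _ = filter_compounds(records, AdmeCriteria(ob_min=42.0, dl_min=0.25))
print(f"tightened screen (OB>=42, DL>=0.25): {len(strict)} active:")
for r in strict:
    print(f"  {r.name:<16} OB={r.ob:5.2f}%  DL={r.dl:.2f}")
# Every printed compound passes the conventional screen; raising either
# threshold can only shrink the active set (never reorder rejections in).
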