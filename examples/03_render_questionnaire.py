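"""Tailor the final questionnaire to a concrete behavior via TACT mapping.

The items are generic templates; supplying the Target, Action, Context and
Time (plus the innovation and profession labels) yields a fieldable
questionnaire. Here: physiotherapists delivering physical-activity
counseling in primary care.
"""

from dcvkit import TactMapping, packaged_item_bank, render_item

bank = packaged_item_bank()
mapping = TactMapping(
    language="en",
    mapping={
        "A": "deliver physical activity counseling",
        "C": "primary care",
        "T": "the coming month",
        "Ta": "my patients",
        "innovation": "the PA counseling program",
        "profession": "physiotherapist",
    },
)

print(f"{len(bank.final_items)} validated items:\n")
for item in bank.final_items:
    print(f"[{'/'.join(item.intended_domains)}] {render_item(item, mapping)}")
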