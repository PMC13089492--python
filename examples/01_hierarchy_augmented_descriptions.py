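"""Build hierarchy-augmented (HA) descriptions for a small ICD-style chain.

An HA description chains a code's label to its ancestors with "is"
sentences, giving a sentence encoder the structural context the bare
label lacks.
"""

from icdmap import Code, CodeSystem, build_ha_description

system = CodeSystem(
    "icd9-fragment",
    [
        Code("001-139", "Infectious and parasitic diseases", "", "ch1"),
        Code("001-009", "Intestinal infectious diseases", "001-139", "ch1"),
        Code("001", "Cholera", "001-009", "ch1"),
        Code("001.0", "Cholera due to V. cholerae", "001", "ch1"),
    ],
)

for code_id in ["001-139", "001", "001.0"]:
    ha = build_ha_description(system, code_id)
    print(f"{code_id}: {ha.text}")

# The leaf renders one "is" sentence per ancestor, ending at the chapter
# title; a chapter root renders as its bare label.
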