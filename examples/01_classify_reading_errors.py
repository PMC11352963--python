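"""Classify individual reading errors into weighted dyslexia codes.

Each target/response pair is aligned at the grapheme level and every
discrepancy is labelled with an error type (substitution, migration,
stress shift, ...), the unit affected (vowel, consonant, voicing feature,
...), its within-word position, and a weight: when one discrepancy admits
several readings they share the weight as "or" alternatives.
"""

from lettura import (
    CodingContext,
    CodingResources,
    ListId,
    ResponseRecord,
    StimulusItem,
    Sublist,
    classify_response,
)

CASES = [
    # (target, response, list, sublist, context, note)
    ("lardo", "ladro", ListId.WORD, Sublist.MIGRATABLE, None,
     "anagram reading -> within-word letter migration"),
    ("prati", "pirati", ListId.WORD, Sublist.MIGRATABLE,
     CodingContext(below_text="circo"),
     "added 'i' also sits at position 2 of the line below -> two-way 'or'"),
    ("abate", "abete", ListId.WORD, Sublist.VOWEL_NEIGHBOR, None,
     "vowel substitution producing an existing word (lexicalized)"),
    ("vondesta", "voldestra", ListId.NONWORD, Sublist.PLAIN_NONWORD, None,
     "two independent errors -> two 'and' groups of weight 1"),
]

resources = CodingResources(lexicon={"abate", "abete", "ladro", "pirati"})

for target, response, list_id, sublist, ctx, note in CASES:
    item = StimulusItem("x", target, list_id, sublist)
    record = ResponseRecord("demo", 4, "x", response)
    coded = classify_response(item, record, ctx, resources)
    print(f"{target} -> {response}   ({note})")
    for g, group in enumerate(coded.groups):
        for code in group:
            print(
                f"  group {g}: {code.etype.value:24s} unit={code.unit.value:16s}"
                f" weight={code.weight}  lexicalized={code.lexicalized}"
            )
    print()
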