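# Default transformation-rule templates: one per line, condition slots
# joined by '&'. A slot is feature@offset; 'tag' refers to the current
# working tags (re-evaluated as rules rewrite them), every other feature
# is computed once from the text.
token@0
token@0 & tag@-1
length@-1 & token@0
all_digits@0 & pos@0
prefix4@0
suffix4@0
section@0 & all_digits@0
token@-1
token@1
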