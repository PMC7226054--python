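# Default feature-cross inventory: 49 composites over token/shape/POS/section
# features in a -1..+1 window. One cross per line; members joined by '&'.
token@-1 & token@0
token@0 & token@1
token@-1 & token@1
all_digits@0 & init_upper@-1
all_digits@0 & init_upper@1
all_digits@-1 & all_digits@0
all_digits@0 & all_digits@1
all_digits@-1 & all_digits@1
init_upper@-1 & init_upper@0
init_upper@0 & init_upper@1
init_upper@-1 & init_upper@1
length@-1 & length@0
length@0 & length@1
length@-1 & length@1
token@0 & all_digits@-1
token@0 & all_digits@1
token@0 & init_upper@-1
token@0 & init_upper@1
token@0 & length@-1
token@0 & length@1
token@-1 & all_digits@0
token@1 & all_digits@0
token@-1 & init_upper@0
token@1 & init_upper@0
token@-1 & length@0
token@1 & length@0
pos@-1 & pos@0
pos@0 & pos@1
pos@-1 & pos@1
token@0 & pos@-1
token@0 & pos@1
pos@0 & token@-1
pos@0 & token@1
all_digits@0 & pos@0
all_digits@0 & pos@-1
all_digits@0 & pos@1
init_upper@0 & pos@0
length@0 & pos@0
section@0 & token@0
section@0 & all_digits@0
section@0 & init_upper@0
section@0 & length@0
section@0 & pos@0
all_digits@0 & length@0
init_upper@0 & length@0
all_digits@0 & init_upper@0
token@-1 & token@0 & token@1
all_digits@-1 & all_digits@0 & all_digits@1
init_upper@0 & all_digits@-1 & all_digits@1
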