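# Default initial-annotator patterns: priority <TAB> regex <TAB> tag.
# Lower priority number wins conflicts. Lines 10-14 are the published
# pattern table, kept verbatim (note the DATE alternation repeats \d{4};
# the oddity is preserved deliberately, it is harmless to the matcher).
# Lines 1-6 add structured-PHI patterns so dates with separators, phone
# numbers, record numbers and zip codes are caught whole before the
# generic rows below get a chance to tag their fragments.
1	\d{2}/\d{2}/\d{4}	B(DATE)
2	\d{4}-\d{2}-\d{2}	B(DATE)
3	\(\d{3}\) ?\d{3}-\d{4}	B(PHONE)
4	\d{3}-\d{3}-\d{4}	B(PHONE)
5	\d{7}	B(MEDICALRECORD)
6	\d{5}	B(ZIP)
10	[A-Za-z]{2,3} [0-9]{2,3}	B(USERNAME)
11	Hospital|HOSPITAL	I(HOSPITAL)
12	\w+@\w+\.[A-Za-z]{3}	B(EMAIL)
13	St|Street|Avenue|Lane|Drive|Rd|Road|Circle|Place	I(STREET)
14	\d{4}|\d{2}-\d{2}-\d{2}|\d{4}	B(DATE)
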