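id	name	synonyms	gender_female_fraction	onset_age	prevalence	system_label
sle	systemic lupus erythematosus	lupus				multiple
sjogren	Sjögren's syndrome	Sjögren				multiple
t1d	type 1 diabetes	type I diabetes				endocrine
aitd	autoimmune thyroid disease	autoimmune thyroiditis				endocrine
ra	rheumatoid arthritis					musculoskeletal
ms	multiple sclerosis					neuronal
ssc	systemic sclerosis	scleroderma				cutaneous
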