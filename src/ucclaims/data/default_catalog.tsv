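drug_id	display_name	drug_class	route	rule	rule_param
mesalazine	5-ASA (mesalazine)	5-ASA	po	prescription_days
prednisolone_po	Prednisolone (oral)	systemic_steroid	po	prescription_days
prednisolone_iv	Prednisolone (intravenous)	systemic_steroid	iv	prescription_days
budesonide_enema	Topical steroid (budesonide foam/enema)	topical_steroid	po	prescription_days
azathioprine	Azathioprine	immunomodulator	po	prescription_days
mercaptopurine	6-Mercaptopurine	immunomodulator	po	prescription_days
infliximab	Infliximab	biologic	iv	fixed_weeks	8
adalimumab	Adalimumab	biologic	sc	count_times_14
golimumab	Golimumab	biologic	sc	count_times_14
ustekinumab	Ustekinumab	biologic	sc	fixed_weeks	12
vedolizumab	Vedolizumab	biologic	iv	fixed_weeks	8
tofacitinib	Tofacitinib	small_molecule	po	prescription_days
tacrolimus	Tacrolimus	small_molecule	po	prescription_days
ciclosporin_po	Cyclosporine (oral)	small_molecule	po	prescription_days
ciclosporin_iv	Cyclosporine (intravenous)	small_molecule	iv	prescription_days
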