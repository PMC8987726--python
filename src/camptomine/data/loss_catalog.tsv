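name	formula	nominal
dehydrogenation	H2	2
methylene	CH2	14
oxygen	O	16
ammonia	NH3	17
water	H2O	18
carbon_monoxide	CO	28
formyl	CHO	29
formaldehyde	CH2O	30
methanol	CH4O	32
propene	C3H6	42
ketene	C2H2O	42
carbon_dioxide	CO2	44
propynal	C3H2O	54
propenal	C3H4O	56
butenal	C4H6O	70
metaphosphoric_acid	HPO3	80
glyceraldehyde	C3H6O3	90
furanone	C5H4O2	96
phosphoric_acid	H3PO4	98
hydroxyquinone	C6H4O3	124
glycerophosphate	C2H7O5P	142
anhydroglucose	C6H10O5	162
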