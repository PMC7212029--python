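wnt_negative_regulators	Wnt negative feedback regulator genes	AXIN2	NKD1	APCDD1	NOTUM	DKK4
wnt_global_responsive	synthetic placeholder for the global Wnt-responsive target set	BG001	BG002	BG003	BG004	BG005	BG006	BG007	BG008	BG009	BG010	BG011	BG012	BG013	BG014	BG015
wnt_stem_cell	synthetic placeholder for the crypt-base columnar stem-cell target set	BG016	BG017	BG018	BG019	BG020	BG021	BG022	BG023	BG024	BG025
wnt_proliferative	synthetic placeholder for the proliferative-cell target set	BG026	BG027	BG028	BG029	BG030	BG031	BG032	BG033	BG034	BG035
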