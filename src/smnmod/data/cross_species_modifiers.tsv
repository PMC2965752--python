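gene_worm	gene_fly	origin	assay	worm_perturbation	worm_effect	fly_perturbation	fly_effect
plst-1	Fim	human	growth	rnai	complex	lof	enhance
plst-1	Fim	human	pumping	rnai	enhance	lof	enhance
daf-4	Wit	fly_screen	pumping	rnai	enhance	lof	enhance
kcnl-2	SK	fly_screen	growth	rnai	enhance	lof	enhance
kcnl-2	SK	fly_screen	pumping	rnai	suppress	lof	enhance
nhr-25	Usp	fly_screen	pumping	rnai	suppress	oe	enhance
uso-1	p115	fly_screen	growth	rnai	enhance	oe	suppress
nhr-85	Eip75B	fly_screen	growth	rnai	enhance	lof	enhance
atf-6	Atf6	fly_screen	growth	rnai	enhance	unknown	suppress
egl-15	Btl	fly_screen	growth	rnai	enhance	lof	enhance
ape-1	CG18375	fly_screen	growth	rnai	enhance	unknown	enhance
nekl-3	Nek2	fly_screen	growth	rnai	enhance	oe	suppress
atn-1	Actinin	fly_screen	growth	rnai	suppress	oe	enhance
cash-1	CG33172	fly_screen	growth	rnai	complex	lof	enhance
dlc-1	cut-up	fly_screen	growth	rnai	complex	lof	suppress
ncbp-2	CBC20	ce_screen	growth	rnai	enhance	lof	enhance
ncbp-2	CBC20	ce_screen	pumping	rnai	enhance	lof	enhance
grk-2	Gprk	ce_screen	growth	rnai	enhance	unknown	not_determined
grk-2	Gprk	ce_screen	pumping	rnai	enhance	unknown	not_determined
flp-4	FMRF	ce_screen	growth	rnai	enhance	lof	enhance
T02G5.3	none	ce_screen	growth	rnai	enhance	unknown	not_determined
T02G5.3	none	ce_screen	pumping	rnai	suppress	unknown	not_determined
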