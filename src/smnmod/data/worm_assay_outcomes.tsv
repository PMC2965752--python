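gene_worm	gene_fly	origin	assay	arm	value	sem	significant	direction
none	none	control	growth	homozygous	18	2	False	none
none	none	control	growth	heterozygous	46	1	False	none
Cesmn-1	Smn	positive_control	growth	homozygous	6	4	True	decrease
Cesmn-1	Smn	positive_control	growth	heterozygous	31	1	True	decrease
plst-1	Fim	human	growth	homozygous	15	3	False	none
plst-1	Fim	human	growth	heterozygous	55	3	True	increase
uso-1	p115	fly_screen	growth	homozygous	7	4	True	decrease
uso-1	p115	fly_screen	growth	heterozygous	44	1	False	none
nhr-85	Eip75B	fly_screen	growth	homozygous	8	5	True	decrease
nhr-85	Eip75B	fly_screen	growth	heterozygous	44	1	False	none
egl-15	Btl	fly_screen	growth	homozygous	9	5	True	decrease
egl-15	Btl	fly_screen	growth	heterozygous	45	1	False	none
atf-6	Atf6	fly_screen	growth	homozygous	11	7	True	decrease
atf-6	Atf6	fly_screen	growth	heterozygous	40	4	False	none
ape-1	CG18375	fly_screen	growth	homozygous	11	9	True	decrease
ape-1	CG18375	fly_screen	growth	heterozygous	50	2	False	none
kcnl-2	SK	fly_screen	growth	homozygous	12	1	True	decrease
kcnl-2	SK	fly_screen	growth	heterozygous	42	1	False	none
nekl-3	Nek2	fly_screen	growth	homozygous	13	3	True	decrease
nekl-3	Nek2	fly_screen	growth	heterozygous	43	2	False	none
atn-1	Actinin	fly_screen	growth	homozygous	23	4	True	increase
atn-1	Actinin	fly_screen	growth	heterozygous	43	1	False	none
cash-1	CG33172	fly_screen	growth	homozygous	26	5	False	none
cash-1	CG33172	fly_screen	growth	heterozygous	64	11	True	increase
dlc-1	cut-up	fly_screen	growth	homozygous	15	8	False	none
dlc-1	cut-up	fly_screen	growth	heterozygous	66	3	True	increase
Cesmn-1	Smn	positive_control	pumping	homozygous	56	19	True	decrease
Cesmn-1	Smn	positive_control	pumping	heterozygous	101	2	False	none
plst-1	Fim	human	pumping	homozygous	86	21	True	decrease
plst-1	Fim	human	pumping	heterozygous	106	1	False	none
daf-4	Wit	fly_screen	pumping	homozygous	71	27	True	decrease
daf-4	Wit	fly_screen	pumping	heterozygous	93	2	False	none
kcnl-2	SK	fly_screen	pumping	homozygous	147	50	True	increase
kcnl-2	SK	fly_screen	pumping	heterozygous	90	1	False	none
nhr-25	Usp	fly_screen	pumping	homozygous	155	45	True	increase
nhr-25	Usp	fly_screen	pumping	heterozygous	91	5	False	none
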