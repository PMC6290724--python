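network	name	abbrev	x	y	z	radius
DMN	Left hippocampal formation	lHF	-21	-15	-14	6
DMN	Right hippocampal formation	rHF	24	-19	-21	6
DMN	Ventromedial prefrontal cortex	vmPFC	0	51	-7	6
DMN	Posterior cingulate cortex	PCC	1	-55	17	6
DMN	Left posterior inferior parietal lobule	lpIPL	-47	-71	29	6
DMN	Right posterior inferior parietal lobule	rpIPL	50	-64	27	6
DAN	Left middle temporal area	lMT	-45	-69	-2	6
DAN	Right middle temporal area	rMT	50	-69	-3	6
DAN	Left intraparietal sulcus	lIPS	-27	-52	57	6
DAN	Right intraparietal sulcus	rIPS	24	-56	55	6
DAN	Left frontal eye field	lFEF	-25	-8	50	6
DAN	Right frontal eye field	rFEF	27	-8	50	6
FPCN	Left anterior prefrontal cortex	laPFC	-36	57	9	6
FPCN	Right anterior prefrontal cortex	raPFC	34	52	10	6
FPCN	Anterior cingulate cortex	ACC	3	31	27	6
FPCN	Left anterior inferior parietal lobule	laIPL	-52	-49	47	6
FPCN	Right anterior inferior parietal lobule	raIPL	52	-46	46	6
FPCN	Left dorsolateral prefrontal cortex	ldlPFC	-50	20	34	6
FPCN	Right dorsolateral prefrontal cortex	rdlPFC	46	14	43	6
FPCN	Left insula	lINS	-31	21	-1	6
FPCN	Right insula	rINS	31	22	-2	6
AN	Left superior temporal gyrus	lSTG	-57	-24	13	6
AN	Right superior temporal gyrus	rSTG	60	-24	13	6
AN	Left Heschl's gyrus	lHes	-45	-15	9	6
AN	Right Heschl's gyrus	rHes	45	-18	9	6
SMN	Left precentral gyrus	lPreC	-41	-4	54	6
SMN	Right precentral gyrus	rPreC	42	-13	53	6
SMN	Left postcentral gyrus	lPoC	-45	-26	54	6
SMN	Right postcentral gyrus	rPoC	49	-27	53	6
SMN	Supplementary motor area	SMA	6	-5	54	6
VN	Left calcarine fissure	lCal	-8	-72	4	6
VN	Right calcarine fissure	rCal	16	-67	5	6
VN	Left cuneus	lCS	-5	-96	12	6
VN	Right cuneus	rCS	18	-96	12	6
VN	Left lateral occipital	lLO	-23	-89	12	6
VN	Right lateral occipital	rLO	37	-85	13	6
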