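isotype	family	species	span_start	span_end	sequence	terminal_met	printed_mh
TUA1	TUA	Pd	414	451	EEGEFSEAREDLAALEKDYEEVGAESPDGEDGDEGDEY	0	4180.691
TUA2	TUA	Pd	414	450	EEGEFSEAREDLAALEKDYEEVGAEGVDDEEDNEDYE	0	4224.717
TUA3	TUA	Pd	414	451	EEGEFSEAREDLAALEKDYEEVGAETAEGDDEEGEEYM	1	4222.738
TUA4	TUA	Pd	414	450	EEGEFSEAREDLAALEKDYEEVGAEGVDDEEEGDDYQ	0	4166.712
TUA5	TUA	Pd	414	451	EEGEFSEAREDLAALEKDYEEVGAESAEGDDDDGDEYM	1	4166.675
TUA6	TUA	Pd	414	449	EEGEFSEAREDLAALEKDYEEVGAEGGDEEGEEEDY	0	4024.637
TUA7	TUA	Pd	414	451	EEGEFSEAREDLAALEKDYEEVGAESAEGEDDDGEEYM	1	4194.707
TUA8	TUA	Pd	414	449	EEGEFSEAREDLAALEKDYEEVGAEGGDDEGEDEDY	0	3996.606
TUB1	TUB	Pd	416	449	NDLVSEYQQYQDATADEEGEYEDEEEGEYQGDYQ	0	4038.559
TUB2	TUB	Pd	416	450	NDLVSEYQQYQDATADEEGEYEEEEEGEEYQQDYQ	0	4252.655
TUB3	TUB	Pd	416	447	NDLVSEYQQYQDATADEEGEFEDEEEAYGDEA	0	3688.400
TUB4	TUB	Pd	416	446	NDLVSEYQQYQDATADEEGEYEDEEAYQDED	0	3690.400
TUB5	TUB	Pd	416	444	NDLVSEYQQYQDATADEDYEDEEEELHDM	1	3475.373
TUB6	TUB	Pd	416	443	NDLVSEYQQYQDATTYEDCEDEEELHDM	1	3364.320
TUB7	TUB	Pd	416	445	NDLVAEYQQYQDATADDEEYEEEEEEEIGA	0	3524.414
TUB8	TUB	Pd	416	445	NDLVAEYQQYQDATIDEEEYEEEEEEEHDT	0	3692.500
TUB9	TUB	Pd	416	442	NDLVSEYQQYQDAVADNEGEYDEEEPM	1	3132.271
TUB10	TUB	Pd	416	444	NDLVSEYQQYQDAAADNDDEYDEEEIVEN	0	3423.378
TUB11	TUB	Pd	416	444	NDLVAEYQQYQDATAEEEIEYEEDDGVEN	0	3408.403
TUB12	TUB	Pd	416	444	NDLVAEYQQYQDATTEEDIEYEEEDGVEN	0	3438.414
TUB13	TUB	Pd	411	442	NDLVSEYQQYQDATAEDDIDYEDEEEEEAAEM	1	3738.473
TUB14	TUB	Pd	416	446	NDLVSEYQQYQDATADEEVDYEDEEEEEAEM	1	3667.436
TUB15	TUB	Pd	416	445	NDLVSEYQQYQDATVDEELEYEDEEEEEAA	0	3582.456
TUB16	TUB	Pd	416	446	NDLVSEYQQYQDATADEEVDYEDEEEDAAGM	1	3523.390
TUB17	TUB	Pd	416	448	NDLVSEYQQYQDATADEEGEYEDEEDGQYAEQM	1	3843.506
TUB18	TUB	Pd	416	450	NDLVSEYQQYQDATADEEGEYDDEEEEEGQYAEQM	1	4101.591
TUB19	TUB	Pd	419	449	NDLVAEYQQYQDATIEEDGEYEEEGEENYDA	0	3658.462
TUB20	TUB	Pd	419	449	NDLVAEYQQYQDATVEEDGEYEEEGEENYDD	0	3688.400
TUA1	TUA	Pta	414	451	EEGEFSEAREDLAALEKDYEEVGAESPDGEDGDEGDEY	0	4180.691
TUA2	TUA	Pta	414	450	EEGEFSEAREDLAALEKDYEEVGAEGVDDEEDNEDYE	0	4224.717
TUA3	TUA	Pta	414	451	EEGEFSEAREDLAALEKDYEEVGAESAEGDDEDGEEYM	1	4194.707
TUA4	TUA	Pta	414	450	EEGEFSEAREDLAALEKDYEEVGAEGVDDEEEGDDYQ	0	4166.712
TUA5	TUA	Pta	414	451	EEGEFSEAREDLAALEKDYEEVGAESAEGDDDDGDEYM	1	4166.675
TUA6	TUA	Pta	414	449	EEGEFSEAREDLAALEKDYEEVGAEGGDEEGEEEDY	0	4024.637
TUA7	TUA	Pta	414	451	EEGEFSEAREDLAALEKDYEEVGAESAEGEDDEGEEYM	1	4208.722
TUA8	TUA	Pta	414	449	EEGEFSEAREDLAALEKDYEEVGAEGGDDEGEDEDY	0	3996.606
TUB1	TUB	Pta	416	449	NDLVSEYQQYQDATADEEGEYEDEEEGEYQGDYQ	0	4038.559
TUB2	TUB	Pta	416	450	NDLVSEYQQYQDATADEEGEYEEEEEGDEYQQDYQ	0	4238.630
TUB3	TUB	Pta	416	447	NDLVSEYQQYQDATADEEGEFEDEEEAYGDEA	0	3688.400
TUB4	TUB	Pta	416	446	NDLVSEYQQYQDATADEEGEYEDEEAYQDED	0	3690.400
TUB5	TUB	Pta	416	444	NDLVSEYQQYQDATADEDYEDEEEELHDM	1	3475.373
TUB6	TUB	Pta	416	443	NDLVSEYQQYQDATTYEDCEDEEELHDM	1	3364.320
TUB7	TUB	Pta	416	445	NDLVAEYQQYQDATADDEEYEEEEEEEIGA	0	3524.414
TUB8	TUB	Pta	416	445	NDLVAEYQQYQDATIDEEEYEEEEEEEHDT	0	3692.500
TUB9	TUB	Pta	416	442	NDLVSEYQQYQDAAADNEGEYDEEEPM	1	3104.240
TUB10	TUB	Pta	416	442	NDLVSEYQQYQDAAADNDDEYDEEEAM	1	3122.214
TUB11	TUB	Pta	416	444	NDLVAEYQQYQDATAEEEIEYEEDDGVEN	0	3408.403
TUB12	TUB	Pta	416	444	NDLVAEYQQYQDATTEEDIEYEEEDGVEN	0	3438.414
TUB13	TUB	Pta	411	442	NDLVSEYQQYQDATAEDDIDYEDEEEEEAAEM	1	3738.473
TUB14	TUB	Pta	416	446	NDLVSEYQQYQDATADEEVDYEDEEEEEAEM	1	3667.436
TUB15	TUB	Pta	416	445	NDLVSEYQQYQDATVDEELEYEDEEEEEAA	0	3582.456
TUB16	TUB	Pta	416	446	NDLVSEYQQYQDATAEEEVDYEDEEEDAAGM	1	3537.410
TUB17	TUB	Pta	416	448	NDLVSEYQQYQDATADEEGEYEDEEDGQYAEQM	1	3843.506
TUB18	TUB	Pta	416	448	NDLVSEYQQYQDATADEEGEYDDEEEEEGQYAE	0	3890.496
TUB19	TUB	Pta	419	449	NDLVAEYQQYQDATIEEDGEYEEEGEENYDA	0	3658.462
TUB20	TUB	Pta	419	449	NDLVAEYQQYQDATVEEDGEYEVEGEENYDD	0	3658.462
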