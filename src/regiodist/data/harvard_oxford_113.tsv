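label_id	region_name	hemisphere
1	Frontal Pole	Left
2	Insular Cortex	Left
3	Superior Frontal Gyrus	Left
4	Middle Frontal Gyrus	Left
5	Inferior Frontal Gyrus, pars triangularis	Left
6	Inferior Frontal Gyrus, pars opercularis	Left
7	Precentral Gyrus	Left
8	Temporal Pole	Left
9	Superior Temporal Gyrus, anterior division	Left
10	Superior Temporal Gyrus, posterior division	Left
11	Middle Temporal Gyrus, anterior division	Left
12	Middle Temporal Gyrus, posterior division	Left
13	Middle Temporal Gyrus, temporooccipital part	Left
14	Inferior Temporal Gyrus, anterior division	Left
15	Inferior Temporal Gyrus, posterior division	Left
16	Inferior Temporal Gyrus, temporooccipital part	Left
17	Postcentral Gyrus	Left
18	Superior Parietal Lobule	Left
19	Supramarginal Gyrus, anterior division	Left
20	Supramarginal Gyrus, posterior division	Left
21	Angular Gyrus	Left
22	Lateral Occipital Cortex, superior division	Left
23	Lateral Occipital Cortex, inferior division	Left
24	Intracalcarine Cortex	Left
25	Frontal Medial Cortex	Left
26	Juxtapositional Lobule Cortex	Left
27	Subcallosal Cortex	Left
28	Paracingulate Gyrus	Left
29	Cingulate Gyrus, anterior division	Left
30	Cingulate Gyrus, posterior division	Left
31	Precuneous Cortex	Left
32	Cuneal Cortex	Left
33	Frontal Orbital Cortex	Left
34	Parahippocampal Gyrus, anterior division	Left
35	Parahippocampal Gyrus, posterior division	Left
36	Lingual Gyrus	Left
37	Temporal Fusiform Cortex, anterior division	Left
38	Temporal Fusiform Cortex, posterior division	Left
39	Temporal Occipital Fusiform Cortex	Left
40	Occipital Fusiform Gyrus	Left
41	Frontal Operculum Cortex	Left
42	Central Opercular Cortex	Left
43	Parietal Operculum Cortex	Left
44	Planum Polare	Left
45	Heschl's Gyrus	Left
46	Planum Temporale	Left
47	Supracalcarine Cortex	Left
48	Occipital Pole	Left
49	Frontal Pole	Right
50	Insular Cortex	Right
51	Superior Frontal Gyrus	Right
52	Middle Frontal Gyrus	Right
53	Inferior Frontal Gyrus, pars triangularis	Right
54	Inferior Frontal Gyrus, pars opercularis	Right
55	Precentral Gyrus	Right
56	Temporal Pole	Right
57	Superior Temporal Gyrus, anterior division	Right
58	Superior Temporal Gyrus, posterior division	Right
59	Middle Temporal Gyrus, anterior division	Right
60	Middle Temporal Gyrus, posterior division	Right
61	Middle Temporal Gyrus, temporooccipital part	Right
62	Inferior Temporal Gyrus, anterior division	Right
63	Inferior Temporal Gyrus, posterior division	Right
64	Inferior Temporal Gyrus, temporooccipital part	Right
65	Postcentral Gyrus	Right
66	Superior Parietal Lobule	Right
67	Supramarginal Gyrus, anterior division	Right
68	Supramarginal Gyrus, posterior division	Right
69	Angular Gyrus	Right
70	Lateral Occipital Cortex, superior division	Right
71	Lateral Occipital Cortex, inferior division	Right
72	Intracalcarine Cortex	Right
73	Frontal Medial Cortex	Right
74	Juxtapositional Lobule Cortex	Right
75	Subcallosal Cortex	Right
76	Paracingulate Gyrus	Right
77	Cingulate Gyrus, anterior division	Right
78	Cingulate Gyrus, posterior division	Right
79	Precuneous Cortex	Right
80	Cuneal Cortex	Right
81	Frontal Orbital Cortex	Right
82	Parahippocampal Gyrus, anterior division	Right
83	Parahippocampal Gyrus, posterior division	Right
84	Lingual Gyrus	Right
85	Temporal Fusiform Cortex, anterior division	Right
86	Temporal Fusiform Cortex, posterior division	Right
87	Temporal Occipital Fusiform Cortex	Right
88	Occipital Fusiform Gyrus	Right
89	Frontal Operculum Cortex	Right
90	Central Opercular Cortex	Right
91	Parietal Operculum Cortex	Right
92	Planum Polare	Right
93	Heschl's Gyrus	Right
94	Planum Temporale	Right
95	Supracalcarine Cortex	Right
96	Occipital Pole	Right
97	Lateral Ventricle	Left
98	Lateral Ventricle	Right
99	Thalamus	Left
100	Thalamus	Right
101	Caudate	Left
102	Caudate	Right
103	Putamen	Left
104	Putamen	Right
105	Pallidum	Left
106	Pallidum	Right
107	Hippocampus	Left
108	Hippocampus	Right
109	Amygdala	Left
110	Amygdala	Right
111	Accumbens	Left
112	Accumbens	Right
113	Brain-Stem	Midline
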