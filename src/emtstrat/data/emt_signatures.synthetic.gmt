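tumor_tissue_EPI	synthetic placeholder gene list (arm size mirrors the published signature)	CDH1	EPCAM	CLDN3	CLDN4	CLDN7	KRT8	KRT18	KRT19	ESRP1	GRHL2	EPI_TT_001	EPI_TT_002	EPI_TT_003	EPI_TT_004	EPI_TT_005	EPI_TT_006	EPI_TT_007	EPI_TT_008	EPI_TT_009	EPI_TT_010	EPI_TT_011	EPI_TT_012	EPI_TT_013	EPI_TT_014	EPI_TT_015	EPI_TT_016	EPI_TT_017	EPI_TT_018	EPI_TT_019	EPI_TT_020	EPI_TT_021	EPI_TT_022	EPI_TT_023	EPI_TT_024	EPI_TT_025	EPI_TT_026	EPI_TT_027	EPI_TT_028	EPI_TT_029	EPI_TT_030	EPI_TT_031	EPI_TT_032	EPI_TT_033	EPI_TT_034	EPI_TT_035	EPI_TT_036	EPI_TT_037	EPI_TT_038	EPI_TT_039	EPI_TT_040	EPI_TT_041	EPI_TT_042	EPI_TT_043	EPI_TT_044	EPI_TT_045	EPI_TT_046	EPI_TT_047	EPI_TT_048	EPI_TT_049	EPI_TT_050	EPI_TT_051	EPI_TT_052	EPI_TT_053	EPI_TT_054	EPI_TT_055	EPI_TT_056	EPI_TT_057	EPI_TT_058	EPI_TT_059	EPI_TT_060	EPI_TT_061	EPI_TT_062	EPI_TT_063	EPI_TT_064	EPI_TT_065	EPI_TT_066	EPI_TT_067	EPI_TT_068	EPI_TT_069	EPI_TT_070	EPI_TT_071	EPI_TT_072	EPI_TT_073	EPI_TT_074	EPI_TT_075	EPI_TT_076	EPI_TT_077	EPI_TT_078	EPI_TT_079	EPI_TT_080	EPI_TT_081	EPI_TT_082	EPI_TT_083	EPI_TT_084	EPI_TT_085	EPI_TT_086	EPI_TT_087	EPI_TT_088	EPI_TT_089	EPI_TT_090	EPI_TT_091	EPI_TT_092	EPI_TT_093	EPI_TT_094	EPI_TT_095	EPI_TT_096	EPI_TT_097	EPI_TT_098	EPI_TT_099	EPI_TT_100	EPI_TT_101	EPI_TT_102	EPI_TT_103	EPI_TT_104	EPI_TT_105	EPI_TT_106	EPI_TT_107	EPI_TT_108	EPI_TT_109	EPI_TT_110	EPI_TT_111	EPI_TT_112	EPI_TT_113	EPI_TT_114	EPI_TT_115	EPI_TT_116	EPI_TT_117	EPI_TT_118	EPI_TT_119	EPI_TT_120	EPI_TT_121	EPI_TT_122	EPI_TT_123	EPI_TT_124	EPI_TT_125	EPI_TT_126	EPI_TT_127	EPI_TT_128	EPI_TT_129	EPI_TT_130	EPI_TT_131	EPI_TT_132	EPI_TT_133	EPI_TT_134	EPI_TT_135
tumor_tissue_MES	synthetic placeholder gene list (arm size mirrors the published signature)	VIM	CDH2	FN1	SNAI1	SNAI2	TWIST1	TWIST2	ZEB1	ZEB2	MMP2	MMP9	SPARC	MES_TT_001	MES_TT_002	MES_TT_003	MES_TT_004	MES_TT_005	MES_TT_006	MES_TT_007	MES_TT_008	MES_TT_009	MES_TT_010	MES_TT_011	MES_TT_012	MES_TT_013	MES_TT_014	MES_TT_015	MES_TT_016	MES_TT_017	MES_TT_018	MES_TT_019	MES_TT_020	MES_TT_021	MES_TT_022	MES_TT_023	MES_TT_024	MES_TT_025	MES_TT_026	MES_TT_027	MES_TT_028	MES_TT_029	MES_TT_030	MES_TT_031	MES_TT_032	MES_TT_033	MES_TT_034	MES_TT_035	MES_TT_036	MES_TT_037	MES_TT_038	MES_TT_039	MES_TT_040	MES_TT_041	MES_TT_042	MES_TT_043	MES_TT_044	MES_TT_045	MES_TT_046	MES_TT_047	MES_TT_048	MES_TT_049	MES_TT_050	MES_TT_051	MES_TT_052	MES_TT_053	MES_TT_054	MES_TT_055	MES_TT_056	MES_TT_057	MES_TT_058	MES_TT_059	MES_TT_060	MES_TT_061	MES_TT_062	MES_TT_063	MES_TT_064	MES_TT_065	MES_TT_066	MES_TT_067	MES_TT_068	MES_TT_069	MES_TT_070	MES_TT_071	MES_TT_072	MES_TT_073	MES_TT_074	MES_TT_075	MES_TT_076	MES_TT_077	MES_TT_078	MES_TT_079	MES_TT_080	MES_TT_081	MES_TT_082	MES_TT_083	MES_TT_084	MES_TT_085	MES_TT_086	MES_TT_087	MES_TT_088	MES_TT_089	MES_TT_090	MES_TT_091	MES_TT_092	MES_TT_093	MES_TT_094	MES_TT_095	MES_TT_096	MES_TT_097	MES_TT_098	MES_TT_099	MES_TT_100	MES_TT_101	MES_TT_102	MES_TT_103	MES_TT_104	MES_TT_105	MES_TT_106	MES_TT_107	MES_TT_108	MES_TT_109	MES_TT_110	MES_TT_111	MES_TT_112	MES_TT_113	MES_TT_114	MES_TT_115	MES_TT_116	MES_TT_117	MES_TT_118	MES_TT_119	MES_TT_120	MES_TT_121	MES_TT_122	MES_TT_123	MES_TT_124	MES_TT_125	MES_TT_126	MES_TT_127	MES_TT_128	MES_TT_129	MES_TT_130	MES_TT_131	MES_TT_132	MES_TT_133	MES_TT_134	MES_TT_135	MES_TT_136	MES_TT_137	MES_TT_138	MES_TT_139	MES_TT_140	MES_TT_141	MES_TT_142	MES_TT_143	MES_TT_144	MES_TT_145	MES_TT_146	MES_TT_147	MES_TT_148	MES_TT_149	MES_TT_150	MES_TT_151	MES_TT_152	MES_TT_153	MES_TT_154	MES_TT_155	MES_TT_156	MES_TT_157	MES_TT_158
cell_line_EPI	synthetic placeholder gene list (arm size mirrors the published signature)	CDH1	EPCAM	CLDN3	CLDN4	CLDN7	KRT8	KRT18	KRT19	ESRP1	GRHL2	EPI_CL_001	EPI_CL_002	EPI_CL_003	EPI_CL_004	EPI_CL_005	EPI_CL_006	EPI_CL_007	EPI_CL_008	EPI_CL_009	EPI_CL_010	EPI_CL_011	EPI_CL_012	EPI_CL_013	EPI_CL_014	EPI_CL_015	EPI_CL_016	EPI_CL_017	EPI_CL_018	EPI_CL_019	EPI_CL_020	EPI_CL_021	EPI_CL_022	EPI_CL_023	EPI_CL_024	EPI_CL_025	EPI_CL_026	EPI_CL_027	EPI_CL_028	EPI_CL_029	EPI_CL_030	EPI_CL_031	EPI_CL_032	EPI_CL_033	EPI_CL_034	EPI_CL_035	EPI_CL_036	EPI_CL_037	EPI_CL_038	EPI_CL_039	EPI_CL_040	EPI_CL_041	EPI_CL_042	EPI_CL_043	EPI_CL_044	EPI_CL_045	EPI_CL_046	EPI_CL_047	EPI_CL_048	EPI_CL_049	EPI_CL_050	EPI_CL_051	EPI_CL_052	EPI_CL_053	EPI_CL_054	EPI_CL_055	EPI_CL_056	EPI_CL_057	EPI_CL_058	EPI_CL_059	EPI_CL_060	EPI_CL_061	EPI_CL_062	EPI_CL_063	EPI_CL_064	EPI_CL_065	EPI_CL_066	EPI_CL_067	EPI_CL_068	EPI_CL_069	EPI_CL_070	EPI_CL_071	EPI_CL_072	EPI_CL_073	EPI_CL_074	EPI_CL_075	EPI_CL_076	EPI_CL_077	EPI_CL_078	EPI_CL_079	EPI_CL_080	EPI_CL_081	EPI_CL_082	EPI_CL_083	EPI_CL_084	EPI_CL_085	EPI_CL_086	EPI_CL_087	EPI_CL_088	EPI_CL_089	EPI_CL_090	EPI_CL_091	EPI_CL_092	EPI_CL_093	EPI_CL_094	EPI_CL_095	EPI_CL_096	EPI_CL_097	EPI_CL_098	EPI_CL_099	EPI_CL_100	EPI_CL_101	EPI_CL_102	EPI_CL_103	EPI_CL_104	EPI_CL_105	EPI_CL_106	EPI_CL_107	EPI_CL_108	EPI_CL_109	EPI_CL_110	EPI_CL_111	EPI_CL_112	EPI_CL_113	EPI_CL_114	EPI_CL_115	EPI_CL_116	EPI_CL_117	EPI_CL_118	EPI_CL_119	EPI_CL_120	EPI_CL_121	EPI_CL_122	EPI_CL_123	EPI_CL_124	EPI_CL_125	EPI_CL_126	EPI_CL_127	EPI_CL_128	EPI_CL_129	EPI_CL_130	EPI_CL_131	EPI_CL_132	EPI_CL_133	EPI_CL_134	EPI_CL_135	EPI_CL_136	EPI_CL_137	EPI_CL_138	EPI_CL_139	EPI_CL_140	EPI_CL_141	EPI_CL_142	EPI_CL_143	EPI_CL_144	EPI_CL_145	EPI_CL_146	EPI_CL_147	EPI_CL_148	EPI_CL_149	EPI_CL_150	EPI_CL_151	EPI_CL_152	EPI_CL_153	EPI_CL_154	EPI_CL_155	EPI_CL_156	EPI_CL_157	EPI_CL_158	EPI_CL_159	EPI_CL_160
cell_line_MES	synthetic placeholder gene list (arm size mirrors the published signature)	VIM	CDH2	FN1	SNAI1	SNAI2	TWIST1	TWIST2	ZEB1	ZEB2	MMP2	MMP9	SPARC	MES_CL_001	MES_CL_002	MES_CL_003	MES_CL_004	MES_CL_005	MES_CL_006	MES_CL_007	MES_CL_008	MES_CL_009	MES_CL_010	MES_CL_011	MES_CL_012	MES_CL_013	MES_CL_014	MES_CL_015	MES_CL_016	MES_CL_017	MES_CL_018	MES_CL_019	MES_CL_020	MES_CL_021	MES_CL_022	MES_CL_023	MES_CL_024	MES_CL_025	MES_CL_026	MES_CL_027	MES_CL_028	MES_CL_029	MES_CL_030	MES_CL_031	MES_CL_032	MES_CL_033	MES_CL_034	MES_CL_035	MES_CL_036
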