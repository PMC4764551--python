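study_label,contrast,bold,bold_se,attended
synthetic_00_gamma0.4,0.02,0.2707670577981158,0.05,False
synthetic_00_gamma0.4,0.034973572431802796,0.4048315214646525,0.05,False
synthetic_00_gamma0.4,0.06115753843212785,0.6655132603618775,0.05,False
synthetic_00_gamma0.4,0.10694488000533932,0.953254695847517,0.05,False
synthetic_00_gamma0.4,0.18701222535385967,1.3005230913497265,0.05,False
synthetic_00_gamma0.4,0.327024280452292,1.681808858806212,0.05,False
synthetic_00_gamma0.4,0.5718603679678211,1.9300683663182354,0.05,False
synthetic_00_gamma0.4,1.0,1.9994376811285308,0.05,False
synthetic_01_gamma0.5,0.02,0.12430368277543039,0.05,True
synthetic_01_gamma0.5,0.034973572431802796,0.2138192573858397,0.05,True
synthetic_01_gamma0.5,0.06115753843212785,0.4440828884858346,0.05,True
synthetic_01_gamma0.5,0.10694488000533932,0.7886745030559154,0.05,True
synthetic_01_gamma0.5,0.18701222535385967,1.0817477277048377,0.05,True
synthetic_01_gamma0.5,0.327024280452292,1.5779575048805268,0.05,True
synthetic_01_gamma0.5,0.5718603679678211,1.7702413513063442,0.05,True
synthetic_01_gamma0.5,1.0,1.9036716325554912,0.05,True
synthetic_02_gamma0.8,0.02,0.007762030659990593,0.05,False
synthetic_02_gamma0.8,0.034973572431802796,0.06882509782582137,0.05,False
synthetic_02_gamma0.8,0.06115753843212785,0.22123766483615054,0.05,False
synthetic_02_gamma0.8,0.10694488000533932,0.5014868546294738,0.05,False
synthetic_02_gamma0.8,0.18701222535385967,0.8744446189726442,0.05,False
synthetic_02_gamma0.8,0.327024280452292,1.452320442704315,0.05,False
synthetic_02_gamma0.8,0.5718603679678211,1.7056072739648032,0.05,False
synthetic_02_gamma0.8,1.0,1.9228907585633663,0.05,False
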