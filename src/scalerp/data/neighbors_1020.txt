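# Neighbor template for a standard 10-20 montage (31 scalp sites).
# Format: ELECTRODE: neighbor neighbor ...   (symmetrized on load)
Fp1: Fp2 F7 F3 Fz
Fp2: Fp1 F8 F4 Fz
F7: Fp1 F3 FC5 T7
F3: Fp1 F7 Fz FC5 FC1
Fz: Fp1 Fp2 F3 F4 FC1 FC2 FCz
F4: Fp2 F8 Fz FC6 FC2
F8: Fp2 F4 FC6 T8
FC5: F7 F3 T7 C3 FC1
FC1: F3 Fz FC5 FCz C3 Cz
FCz: Fz FC1 FC2 Cz
FC2: F4 Fz FC6 FCz C4 Cz
FC6: F8 F4 T8 C4 FC2
T7: F7 FC5 C3 CP5 P7
C3: FC5 FC1 T7 Cz CP5 CP1
Cz: FC1 FCz FC2 C3 C4 CP1 CPz CP2
C4: FC6 FC2 T8 Cz CP6 CP2
T8: F8 FC6 C4 CP6 P8
CP5: T7 C3 CP1 P7 P3
CP1: C3 Cz CP5 CPz P3 Pz
CPz: Cz CP1 CP2 Pz
CP2: C4 Cz CP6 CPz P4 Pz
CP6: T8 C4 CP2 P8 P4
P7: T7 CP5 P3 O1
P3: CP5 CP1 P7 Pz O1
Pz: CP1 CPz CP2 P3 P4 Oz
P4: CP6 CP2 P8 Pz O2
P8: T8 CP6 P4 O2
O1: P7 P3 Oz
Oz: O1 O2 Pz
O2: P8 P4 Oz
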