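# Per-side mean gait speed and step length for a published clinical cohort of 20
# children with bilateral cerebral palsy (GMFCS I-III), measured with a single-camera
# sagittal markerless system. One row per participant-side; participant 19 walked only
# with assistive devices and has no speed/step values.
participant,side,gait_speed_m_s,step_length_m
1,L,0.86,0.46
1,R,0.85,0.48
2,L,0.85,0.43
2,R,0.81,0.49
3,L,0.86,0.40
3,R,0.74,0.38
4,L,0.91,0.42
4,R,0.87,0.44
5,L,0.88,0.49
5,R,0.81,0.49
6,L,0.72,0.25
6,R,0.70,0.48
7,L,0.13,0.12
7,R,0.12,0.13
8,L,0.83,0.41
8,R,0.89,0.41
9,L,0.48,0.31
9,R,0.52,0.30
10,L,0.91,0.44
10,R,0.90,0.41
11,L,0.64,0.32
11,R,0.61,0.39
12,L,0.87,0.45
12,R,0.90,0.42
13,L,0.65,0.36
13,R,0.58,0.34
14,L,0.27,0.30
14,R,0.30,0.29
15,L,0.73,0.37
15,R,0.81,0.36
16,L,0.60,0.36
16,R,0.62,0.35
17,L,0.52,0.31
17,R,0.27,0.24
18,L,0.82,0.39
18,R,0.86,0.38
19,L,,
19,R,,
20,L,0.73,0.38
20,R,0.74,0.40
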