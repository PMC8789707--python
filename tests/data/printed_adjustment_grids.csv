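scale,education,age,printed
FAB,5,35,0.28
FAB,5,40,0.36
FAB,5,45,0.47
FAB,5,50,0.61
FAB,5,55,0.77
FAB,5,60,0.97
FAB,5,65,1.21
FAB,5,70,1.48
FAB,5,75,1.79
FAB,5,80,2.15
FAB,5,85,2.56
FAB,5,90,3.02
FAB,5,95,3.54
FAB,8,35,-0.46
FAB,8,40,-0.37
FAB,8,45,-0.26
FAB,8,50,-0.13
FAB,8,55,0.04
FAB,8,60,0.23
FAB,8,65,0.47
FAB,8,70,0.74
FAB,8,75,1.06
FAB,8,80,1.42
FAB,8,85,1.83
FAB,8,90,2.29
FAB,8,95,2.8
FAB,11,35,-0.96
FAB,11,40,-0.87
FAB,11,45,-0.76
FAB,11,50,-0.63
FAB,11,55,-0.46
FAB,11,60,-0.26
FAB,11,65,-0.03
FAB,11,70,0.24
FAB,11,75,0.56
FAB,11,80,0.92
FAB,11,85,1.33
FAB,11,90,1.79
FAB,11,95,2.3
FAB,13,35,-1.22
FAB,13,40,-1.13
FAB,13,45,-1.02
FAB,13,50,-0.89
FAB,13,55,-0.72
FAB,13,60,-0.53
FAB,13,65,-0.29
FAB,13,70,-0.02
FAB,13,75,0.3
FAB,13,80,0.66
FAB,13,85,1.07
FAB,13,90,1.53
FAB,13,95,2.04
FAB,16,35,-1.54
FAB,16,40,-1.46
FAB,16,45,-1.35
FAB,16,50,-1.21
FAB,16,55,-1.05
FAB,16,60,-0.85
FAB,16,65,-0.62
FAB,16,70,-0.34
FAB,16,75,-0.03
FAB,16,80,0.33
FAB,16,85,0.74
FAB,16,90,1.2
FAB,16,95,1.71
FAB,18,35,-1.73
FAB,18,40,-1.64
FAB,18,45,-1.53
FAB,18,50,-1.4
FAB,18,55,-1.23
FAB,18,60,-1.03
FAB,18,65,-0.8
FAB,18,70,-0.53
FAB,18,75,-0.21
FAB,18,80,0.15
FAB,18,85,0.56
FAB,18,90,1.02
FAB,18,95,1.53
FAB,21,35,-1.97
FAB,21,40,-1.88
FAB,21,45,-1.78
FAB,21,50,-1.64
FAB,21,55,-1.47
FAB,21,60,-1.28
FAB,21,65,-1.04
FAB,21,70,-0.77
FAB,21,75,-0.45
FAB,21,80,-0.09
FAB,21,85,0.32
FAB,21,90,0.78
FAB,21,95,1.29
FAB1,5,35,0.23
FAB1,5,40,0.25
FAB1,5,45,0.28
FAB1,5,50,0.32
FAB1,5,55,0.36
FAB1,5,60,0.41
FAB1,5,65,0.46
FAB1,5,70,0.53
FAB1,5,75,0.61
FAB1,5,80,0.7
FAB1,5,85,0.8
FAB1,5,90,0.92
FAB1,5,95,1.05
FAB1,8,35,-0.05
FAB1,8,40,-0.03
FAB1,8,45,
FAB1,8,50,
FAB1,8,55,0.07
FAB1,8,60,0.12
FAB1,8,65,0.18
FAB1,8,70,0.25
FAB1,8,75,0.33
FAB1,8,80,0.42
FAB1,8,85,0.52
FAB1,8,90,0.63
FAB1,8,95,0.76
FAB1,11,35,-0.25
FAB1,11,40,-0.22
FAB1,11,45,-0.2
FAB1,11,50,-0.16
FAB1,11,55,-0.12
FAB1,11,60,-0.07
FAB1,11,65,-0.01
FAB1,11,70,0.05
FAB1,11,75,0.13
FAB1,11,80,0.22
FAB1,11,85,0.33
FAB1,11,90,0.44
FAB1,11,95,0.57
FAB1,13,35,-0.35
FAB1,13,40,-0.33
FAB1,13,45,-0.3
FAB1,13,50,-0.27
FAB1,13,55,-0.22
FAB1,13,60,-0.17
FAB1,13,65,-0.12
FAB1,13,70,-0.05
FAB1,13,75,0.03
FAB1,13,80,0.12
FAB1,13,85,0.22
FAB1,13,90,0.34
FAB1,13,95,0.47
FAB1,16,35,-0.47
FAB1,16,40,-0.45
FAB1,16,45,-0.43
FAB1,16,50,-0.39
FAB1,16,55,-0.35
FAB1,16,60,-0.3
FAB1,16,65,-0.24
FAB1,16,70,-0.17
FAB1,16,75,-0.09
FAB1,16,80,
FAB1,16,85,
FAB1,16,90,0.21
FAB1,16,95,0.34
FAB1,18,35,-0.54
FAB1,18,40,-0.52
FAB1,18,45,-0.5
FAB1,18,50,-0.46
FAB1,18,55,-0.42
FAB1,18,60,-0.37
FAB1,18,65,-0.31
FAB1,18,70,-0.24
FAB1,18,75,-0.17
FAB1,18,80,-0.08
FAB1,18,85,0.03
FAB1,18,90,0.14
FAB1,18,95,0.27
FAB1,21,35,-0.64
FAB1,21,40,-0.62
FAB1,21,45,-0.59
FAB1,21,50,-0.56
FAB1,21,55,-0.52
FAB1,21,60,-0.47
FAB1,21,65,-0.41
FAB1,21,70,-0.34
FAB1,21,75,-0.26
FAB1,21,80,-0.17
FAB1,21,85,-0.07
FAB1,21,90,0.05
FAB1,21,95,0.18
FAB2,5,35,-0.21
FAB2,5,40,-0.17
FAB2,5,45,-0.12
FAB2,5,50,-0.05
FAB2,5,55,0.03
FAB2,5,60,0.13
FAB2,5,65,0.25
FAB2,5,70,0.39
FAB2,5,75,0.54
FAB2,5,80,0.72
FAB2,5,85,0.93
FAB2,5,90,1.16
FAB2,5,95,1.41
FAB2,8,35,-0.4
FAB2,8,40,-0.36
FAB2,8,45,-0.31
FAB2,8,50,-0.24
FAB2,8,55,-0.16
FAB2,8,60,-0.06
FAB2,8,65,0.06
FAB2,8,70,0.2
FAB2,8,75,0.35
FAB2,8,80,0.53
FAB2,8,85,0.74
FAB2,8,90,0.97
FAB2,8,95,1.23
FAB2,11,35,-0.49
FAB2,11,40,-0.45
FAB2,11,45,-0.39
FAB2,11,50,-0.33
FAB2,11,55,-0.24
FAB2,11,60,-0.14
FAB2,11,65,-0.03
FAB2,11,70,0.11
FAB2,11,75,0.27
FAB2,11,80,0.45
FAB2,11,85,0.65
FAB2,11,90,0.88
FAB2,11,95,1.14
FAB2,13,35,-0.53
FAB2,13,40,-0.48
FAB2,13,45,-0.43
FAB2,13,50,-0.36
FAB2,13,55,-0.28
FAB2,13,60,-0.18
FAB2,13,65,-0.06
FAB2,13,70,0.07
FAB2,13,75,0.23
FAB2,13,80,0.41
FAB2,13,85,0.62
FAB2,13,90,0.85
FAB2,13,95,1.1
FAB2,16,35,-0.56
FAB2,16,40,-0.52
FAB2,16,45,-0.47
FAB2,16,50,-0.4
FAB2,16,55,-0.31
FAB2,16,60,-0.22
FAB2,16,65,-0.1
FAB2,16,70,0.04
FAB2,16,75,0.2
FAB2,16,80,0.38
FAB2,16,85,0.58
FAB2,16,90,0.81
FAB2,16,95,1.07
FAB2,18,35,-0.58
FAB2,18,40,-0.54
FAB2,18,45,-0.48
FAB2,18,50,-0.42
FAB2,18,55,-0.33
FAB2,18,60,-0.23
FAB2,18,65,-0.12
FAB2,18,70,0.02
FAB2,18,75,0.18
FAB2,18,80,0.36
FAB2,18,85,0.56
FAB2,18,90,0.79
FAB2,18,95,1.05
FAB2,21,35,-0.6
FAB2,21,40,-0.56
FAB2,21,45,-0.5
FAB2,21,50,-0.44
FAB2,21,55,-0.35
FAB2,21,60,-0.25
FAB2,21,65,-0.14
FAB2,21,70,
FAB2,21,75,
FAB2,21,80,0.34
FAB2,21,85,0.54
FAB2,21,90,0.77
FAB2,21,95,1.03
FAB3,5,35,0.2
FAB3,5,40,0.24
FAB3,5,45,0.29
FAB3,5,50,0.33
FAB3,5,55,0.39
FAB3,5,60,0.45
FAB3,5,65,0.51
FAB3,5,70,0.58
FAB3,5,75,0.66
FAB3,5,80,0.74
FAB3,5,85,0.82
FAB3,5,90,0.91
FAB3,5,95,1.01
FAB3,8,35,-0.1
FAB3,8,40,-0.06
FAB3,8,45,-0.02
FAB3,8,50,0.03
FAB3,8,55,0.09
FAB3,8,60,0.15
FAB3,8,65,0.21
FAB3,8,70,0.28
FAB3,8,75,0.36
FAB3,8,80,0.44
FAB3,8,85,0.52
FAB3,8,90,0.61
FAB3,8,95,0.71
FAB3,11,35,-0.3
FAB3,11,40,-0.26
FAB3,11,45,-0.22
FAB3,11,50,-0.17
FAB3,11,55,-0.12
FAB3,11,60,-0.06
FAB3,11,65,0.01
FAB3,11,70,0.08
FAB3,11,75,0.15
FAB3,11,80,0.23
FAB3,11,85,0.32
FAB3,11,90,0.41
FAB3,11,95,0.5
FAB3,13,35,-0.41
FAB3,13,40,-0.37
FAB3,13,45,-0.33
FAB3,13,50,-0.28
FAB3,13,55,-0.22
FAB3,13,60,-0.16
FAB3,13,65,-0.1
FAB3,13,70,-0.03
FAB3,13,75,0.04
FAB3,13,80,0.12
FAB3,13,85,0.21
FAB3,13,90,0.3
FAB3,13,95,0.39
FAB3,16,35,-0.54
FAB3,16,40,-0.5
FAB3,16,45,-0.46
FAB3,16,50,-0.41
FAB3,16,55,-0.36
FAB3,16,60,-0.3
FAB3,16,65,-0.23
FAB3,16,70,-0.16
FAB3,16,75,-0.09
FAB3,16,80,-0.01
FAB3,16,85,0.08
FAB3,16,90,0.17
FAB3,16,95,0.26
FAB3,18,35,-0.62
FAB3,18,40,-0.58
FAB3,18,45,-0.53
FAB3,18,50,-0.49
FAB3,18,55,-0.43
FAB3,18,60,-0.37
FAB3,18,65,-0.31
FAB3,18,70,-0.24
FAB3,18,75,-0.16
FAB3,18,80,-0.08
FAB3,18,85,
FAB3,18,90,
FAB3,18,95,0.19
FAB3,21,35,-0.72
FAB3,21,40,-0.68
FAB3,21,45,-0.63
FAB3,21,50,-0.58
FAB3,21,55,-0.53
FAB3,21,60,-0.47
FAB3,21,65,-0.41
FAB3,21,70,-0.34
FAB3,21,75,-0.26
FAB3,21,80,-0.18
FAB3,21,85,-0.1
FAB3,21,90,-0.01
FAB3,21,95,0.09
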