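scale,education,age,note
FAB1,8,45,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB1,8,50,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB1,16,80,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB1,16,85,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB2,21,70,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB2,21,75,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB3,18,85,garbled two-cell run adjacent to a zero-valued entry in the printed table
FAB3,18,90,garbled two-cell run adjacent to a zero-valued entry in the printed table
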