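table,grade,label,list_group,M,SD,n,threshold
words,2,Attentional,words,5.4,3.6,74,15
words,2,LetterPosition,words,3.5,2.5,74,10
words,2,Surface,words,6.5,3.0,74,14
words,2,MultiLetter,words,4.5,4.5,74,16
words,2,Vowel,words,8.0,5.9,74,23
words,2,Consonant,words,6.5,5.0,74,19
words,2,Doubling,words,7.9,6.5,74,24
words,2,Total,words,42.7,21.5,74,96
words,2,SurfaceStressList,words,4.8,2.4,74,11
words,2,PairsMigrations,pairs,2.6,2.2,74,8
words,3,Attentional,words,3.8,3.0,65,12
words,3,LetterPosition,words,2.9,2.1,65,8
words,3,Surface,words,4.3,2.9,65,12
words,3,MultiLetter,words,1.9,2.9,65,9
words,3,Vowel,words,5.0,4.9,65,17
words,3,Consonant,words,2.8,3.5,65,12
words,3,Doubling,words,4.3,4.5,65,16
words,3,Total,words,25.4,16.6,65,66
words,3,SurfaceStressList,words,3.1,2.1,65,9
words,3,PairsMigrations,pairs,2.0,2.1,65,8
words,4,Attentional,words,2.4,2.2,93,8
words,4,LetterPosition,words,2.1,1.8,93,7
words,4,Surface,words,4.2,2.8,93,11
words,4,MultiLetter,words,1.4,2.0,93,7
words,4,Vowel,words,3.3,3.3,93,12
words,4,Consonant,words,2.2,2.2,93,8
words,4,Doubling,words,2.5,2.7,93,9
words,4,Total,words,18.2,13.0,93,50
words,4,SurfaceStressList,words,3.2,2.2,93,9
words,4,PairsMigrations,pairs,1.3,1.5,93,5
words,5,Attentional,words,2.3,1.9,80,7
words,5,LetterPosition,words,1.8,1.7,80,6
words,5,Surface,words,4.7,2.3,80,11
words,5,MultiLetter,words,0.8,1.4,80,5
words,5,Vowel,words,3.3,2.7,80,10
words,5,Consonant,words,1.7,2.0,80,7
words,5,Doubling,words,2.0,1.9,80,7
words,5,Total,words,16.8,9.9,80,41
words,5,SurfaceStressList,words,3.5,1.8,80,8
words,5,PairsMigrations,pairs,0.8,1.0,80,4
words,6,Attentional,words,1.6,1.2,129,5
words,6,LetterPosition,words,2.2,1.8,129,7
words,6,Surface,words,3.5,2.1,129,9
words,6,MultiLetter,words,0.5,0.8,129,3
words,6,Vowel,words,2.2,2.0,129,8
words,6,Consonant,words,1.2,1.4,129,5
words,6,Doubling,words,1.3,1.6,129,6
words,6,Total,words,12.5,7.0,129,30
words,6,SurfaceStressList,words,2.8,1.7,129,7
words,6,PairsMigrations,pairs,0.7,0.8,129,3
words,7,Attentional,words,2.0,1.6,56,6
words,7,LetterPosition,words,2.1,2.0,56,7
words,7,Surface,words,2.6,1.7,56,7
words,7,MultiLetter,words,0.5,0.9,56,3
words,7,Vowel,words,3.1,2.1,56,9
words,7,Consonant,words,1.4,1.8,56,6
words,7,Doubling,words,1.9,1.5,56,6
words,7,Total,words,13.7,8.3,56,34
words,7,SurfaceStressList,words,2.0,1.4,56,6
words,7,PairsMigrations,pairs,0.6,0.8,56,3
words,8,Attentional,words,1.9,1.5,64,6
words,8,LetterPosition,words,1.3,1.2,64,5
words,8,Surface,words,2.3,1.9,64,7
words,8,MultiLetter,words,0.4,0.9,64,3
words,8,Vowel,words,2.1,2.0,64,7
words,8,Consonant,words,1.0,1.2,64,4
words,8,Doubling,words,1.2,1.4,64,5
words,8,Total,words,10.5,6.5,64,27
words,8,SurfaceStressList,words,1.8,1.7,64,6
words,8,PairsMigrations,pairs,0.6,0.7,64,3
nonwords,2,Attentional,nonwords,1.6,1.4,74,5
nonwords,2,LetterPosition,nonwords,0.7,0.8,74,3
nonwords,2,MultiLetter,nonwords,1.4,1.7,74,6
nonwords,2,Vowel,nonwords,1.8,1.7,74,6
nonwords,2,Consonant,nonwords,3.4,2.4,74,10
nonwords,2,Doubling,nonwords,2.4,2.1,74,8
nonwords,2,Total,nonwords,11.2,6.2,74,27
nonwords,3,Attentional,nonwords,1.1,1.2,65,4
nonwords,3,LetterPosition,nonwords,0.8,1.0,65,4
nonwords,3,MultiLetter,nonwords,0.6,1.1,65,4
nonwords,3,Vowel,nonwords,1.1,1.5,65,5
nonwords,3,Consonant,nonwords,2.3,2.0,65,8
nonwords,3,Doubling,nonwords,1.3,1.4,65,5
nonwords,3,Total,nonwords,7.4,4.6,65,19
nonwords,4,Attentional,nonwords,0.9,1.1,93,4
nonwords,4,LetterPosition,nonwords,0.4,0.6,93,2
nonwords,4,MultiLetter,nonwords,0.3,0.8,93,3
nonwords,4,Vowel,nonwords,0.9,1.0,93,4
nonwords,4,Consonant,nonwords,1.3,1.5,93,5
nonwords,4,Doubling,nonwords,0.9,1.0,93,4
nonwords,4,Total,nonwords,4.7,3.9,93,15
nonwords,5,Attentional,nonwords,1.0,1.2,80,4
nonwords,5,LetterPosition,nonwords,0.5,0.8,80,3
nonwords,5,MultiLetter,nonwords,0.4,0.7,80,3
nonwords,5,Vowel,nonwords,0.6,0.9,80,3
nonwords,5,Consonant,nonwords,1.2,1.4,80,5
nonwords,5,Doubling,nonwords,0.6,0.9,80,3
nonwords,5,Total,nonwords,4.2,3.5,80,13
nonwords,6,Attentional,nonwords,0.7,0.9,129,3
nonwords,6,LetterPosition,nonwords,0.5,0.8,129,3
nonwords,6,MultiLetter,nonwords,0.3,0.5,129,2
nonwords,6,Vowel,nonwords,0.7,0.9,129,3
nonwords,6,Consonant,nonwords,0.7,1.0,129,4
nonwords,6,Doubling,nonwords,0.7,0.9,129,3
nonwords,6,Total,nonwords,3.5,3.1,129,11
nonwords,7,Attentional,nonwords,0.5,0.8,56,3
nonwords,7,LetterPosition,nonwords,0.4,0.7,56,3
nonwords,7,MultiLetter,nonwords,0.2,0.5,56,2
nonwords,7,Vowel,nonwords,0.6,0.9,56,3
nonwords,7,Consonant,nonwords,0.8,0.9,56,3
nonwords,7,Doubling,nonwords,0.6,0.9,56,3
nonwords,7,Total,nonwords,3.2,3.6,56,12
nonwords,8,Attentional,nonwords,0.5,0.6,64,2
nonwords,8,LetterPosition,nonwords,0.3,0.5,64,2
nonwords,8,MultiLetter,nonwords,0.2,0.6,64,2
nonwords,8,Vowel,nonwords,0.6,1.0,64,4
nonwords,8,Consonant,nonwords,0.5,0.6,64,2
nonwords,8,Doubling,nonwords,0.6,0.8,64,3
nonwords,8,Total,nonwords,2.7,2.6,64,9
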