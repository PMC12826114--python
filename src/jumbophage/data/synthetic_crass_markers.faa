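>synthetic_polymerase synthetic stand-in for the crAssphage DNA polymerase marker
PRDEEYWIQVQNPVVDIHYILESDHKYHHWHIDRSPDGLTREKNEHNANTRPTEDCGPIDRVQRPWHPPDHLYDYCPHNYPDNLMQITQNKQLWFQVNCWHWWDICDNEYARLCKSREPGKFLIDAPLWGWNCSDFVEFFLQFVANACMPYAAPPHLRFVVPRREAMFWCNTPLSLMDGWTIGKSDDFPKIWDRFSHGFCIHHFRANLAIHQTGFPIYGSVDWIDIECESGMVSHRVKDFLSIITSDLMAGGWCPDEIKRNFDGTAMADRQDISYFMNKQTCLWYCCRDVQIYFECFGKHLHFVTLMSMGYWITPAQSMPLCSCDYQGCPWWKLMMMDTDQPRQRFPSWEYKWKHLQPQRIYFQGLTSRVRPKLFHRPTQIWETVYSTRGAAAEKSLIPYPHRICSAPNSPPLMNEGHHQTPPVSQISFVWETDEARNYIGTVFYYGTAPVCPPGGTGIRQCSKAMHQNNLENHNLRCWQPNPPWWMKFLNETRWVRRWLSETRTAIEFNSYQMPTPRMS
>synthetic_terminase synthetic stand-in for the crAssphage terminase marker
MKFNDWIQCGCSNRHERTCLQWWALIIKHIQNLKPFTGPVWRNEDQIQEGKDYLWMSARCLENACSRLYWEDNVMCLPVFNRPQLCFTDPEEHCASKYEFQRVYPELTQQYDDTTWPAFPWAPQFRMTLAGCMQSTRKFVSDCINNDSMSMKVYIVIHGVNDADRDNKLGWLPPKREKPGKFFEYCNLRRLADYYAPNWKVCSSDFSPNPHKMLFWGGRKSFHKPKTRNNHDCGWRSVSFFFSMMVEAPGWHRNRSNYRMRLAPEVIWIKPACWIYWQPTDHQTKMFLCMVHEQEVNLSNQLVNHMCIPRPFYACENHRFWHEENLWWKEGPGTLNSTHTEMDIEKNMPHRQFWVEMVATMHFYGIGNWVKYTQTFFTHPCPHVVHMKWDPRWSGSFKYQDHPSSMLLDRCPHRQYMGPAGAEDHDTEET
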