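# surfaces never tagged by the regex taggers (English-word / acronym
# collisions with element-symbol sequences), v1
In
As
At
He
Be
No
Os
Se
IN
IS
IF
ON
NO
OF
BY
US
UP
SO
HI
OK
PC
IP
CV
IV
VI
CNS
NIH
WHO
YES
NOW
HIV
ICU
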